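"""Build the reference MHBI schema and run the structural quality battery.

The schema holds 7 concept classes and 27 core properties (plus 4 shipped
extension properties); the battery runs 8 clarity and 12 coherence tests,
all of which must pass on the reference build.
"""

from mhbi import build_reference_schema, census, validate
from mhbi.validator import report

schema = build_reference_schema()
c = census(schema)
print(f"concept classes:      {c.concept_classes}")
print(f"core properties:      {c.core_properties}")
print(f"extension properties: {c.extension_properties}")
print(f"term individuals:     {c.term_individuals}")
print()
print(report(validate(schema), "text"))
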