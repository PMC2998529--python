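format-version: 1.2
ontology: worked-fixture

[Term]
id: GO:0000001
name: cell compartment root
namespace: cellular_component

[Term]
id: GO:0000002
name: intracellular region
namespace: cellular_component
is_a: GO:0000001

[Term]
id: GO:0000013
name: membrane region
namespace: cellular_component
is_a: GO:0000001

[Term]
id: GO:0000014
name: organelle region
namespace: cellular_component
is_a: GO:0000002

[Term]
id: GO:0000003
name: cytoplasm-like concept
namespace: cellular_component
is_a: GO:0000014

[Term]
id: GO:0000004
name: membrane complex concept
namespace: cellular_component
is_a: GO:0000013

[Term]
id: GO:0000005
name: cytoplasmic organelle
namespace: cellular_component
is_a: GO:0000003

[Term]
id: GO:0000006
name: cytosol-like part
namespace: cellular_component
is_a: GO:0000003

[Term]
id: GO:0000007
name: organelle subcompartment
namespace: cellular_component
is_a: GO:0000005

[Term]
id: GO:0000008
name: organelle lumen component
namespace: cellular_component
is_a: GO:0000007

[Term]
id: GO:0000009
name: integral membrane assembly
namespace: cellular_component
is_a: GO:0000004

[Term]
id: GO:0000010
name: peripheral membrane assembly
namespace: cellular_component
is_a: GO:0000004

[Term]
id: GO:0000011
name: integral membrane subunit
namespace: cellular_component
is_a: GO:0000009

[Term]
id: GO:0000012
name: peripheral membrane subunit
namespace: cellular_component
is_a: GO:0000010
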