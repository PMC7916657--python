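"""Classify driver genes as oncogenes or tumor suppressors from path signs.

Every simple signed path from a gene to a hallmark phenotype is enumerated;
a path's net sign is the product of its edge signs. Genes whose paths
stimulate proliferation or repress differentiation/apoptosis are oncogenic;
the mirror pattern marks a tumor suppressor; both kinds of evidence mark a
dual gene.
"""

from hallmarknet import classify_graph, load_fixture

fixture = load_fixture("flt3_npm1_dnmt3a")
for gene, cls in classify_graph(fixture.graph).items():
    evidence = ", ".join(
        f"{h}{'+' if s > 0 else '-'}" for h, s in sorted(cls.evidence)
    )
    print(f"{gene:8s} {cls.label.value:17s} [{evidence}]")
# FLT3 comes out an oncogene (all its paths push proliferation up and
# differentiation/apoptosis down); NPM1 and DNMT3A come out tumor
# suppressors — matching their loss-of-function role in AML.
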