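"""Classify each mapped gene's regulation as cis, trans, or both.

Combines the linkage sets from the expression panel with the AS-PCR physical
locations: a regulatory autosome coinciding with the gene's own location is
cis, any other linked autosome is trans.
"""

from flylinkage import run_fixture_report

report = run_fixture_report()

print("gene                 location  linked      class")
for c in report.classes:
    linked = "{" + ",".join(map(str, sorted(c.linked_autosomes))) + "}"
    print(f"{c.gene_id:20s} {c.location:^8d}  {linked:10s}  {c.reg_class}")

n_cis = sum(c.reg_class == "cis_only" for c in report.classes)
n_both = sum(c.reg_class == "cis_plus_trans" for c in report.classes)
print(f"\n{n_cis} gene is regulated purely in cis (its only regulatory autosome is")
print(f"the one it sits on); the other {n_both} combine a cis edge with trans")
print("factors on other autosomes.")
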