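"""Generate a synthetic autosome-substitution panel with known ground truth.

Draws 12 gene architectures (factor autosomes + effect sizes), then emulates
every assay of the design: triplicate expression, NB sequencing counts, raw
Ct values and allele-specific PCR bands, written as a TSV bundle.
"""

import tempfile
from pathlib import Path

from flylinkage import Scenario
from flylinkage.simulate import run_scenario

scenario = Scenario(n_genes=12, seed=42)
outdir = Path(tempfile.mkdtemp(prefix="flylinkage_"))
specs = run_scenario(scenario, outdir)

print(f"wrote {sorted(p.name for p in outdir.iterdir())} to {outdir}")
print("\nground truth (gene -> physical autosome, factor autosomes):")
for s in specs[:6]:
    factors = ",".join(map(str, sorted(s.factor_autosomes))) or "none"
    print(f"  {s.gene_id}: autosome {s.physical_autosome}, factors {{{factors}}}")
# Each factor autosome multiplicatively raises the gene's expression when the
# line carries the resistant-strain (R) allele; substituting it drops
# expression by that factor's 2^beta fold.
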