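"""Screen an evolved pooled sample for novel fixed mutations.

A novel substitution is an allele absent from all five founder strains and
from the pooled ancestor (zero alt reads at >= 10x depth in each) but
nearly fixed (> 90% read frequency) in an evolved line.  This script
plants two such mutations in a synthetic evolved pool and recovers them.
"""

import tempfile
from pathlib import Path

import numpy as np

from wormsweep import (
    GenomeLayout,
    SynthSpec,
    detect_novel_mutations,
    load_snps,
    make_founder_panel,
    make_mosaic_pool,
    mutation_alleles,
)

layout = GenomeLayout((("I", 8), ("II", 6)), window_size_bp=200_000)
spec = SynthSpec(layout=layout, seed=23)
tmp = Path(tempfile.mkdtemp())

planted = [("I", 345_678, 1.0), ("II", 1_013_579, 0.97)]
monitors = [(c, p, *mutation_alleles(c, p)) for c, p, _ in planted]

make_founder_panel(spec, str(tmp / "founders.vcf"), monitor_positions=monitors)
flat = {c: np.full((w, 5), 0.2) for c, w in layout.chromosomes}
make_mosaic_pool(spec, flat, str(tmp / "ancestor.vcf"), sample="ancestor",
                 monitor_positions=monitors)
mosaic = {"I": np.full(8, 2), "II": np.full(6, 4)}
make_mosaic_pool(spec, mosaic, str(tmp / "evolved.vcf"), sample="EE1",
                 novel_mutations=planted)

calls = detect_novel_mutations(
    {"EE1": load_snps(str(tmp / "evolved.vcf"))},
    load_snps(str(tmp / "ancestor.vcf")),
    load_snps(str(tmp / "founders.vcf")),
)
print(calls.to_string(index=False))
print(
    f"\n{len(calls)} call(s); planted {len(planted)}.  Frequencies are pooled"
    "\nread proportions, so a fixed mutation shows ~1.0 minus sequencing error."
)
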