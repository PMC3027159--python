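"""Fisher term enrichment of a PDEG set against the whole transcriptome.

Plants a term carried preferentially by species-specific genes, then checks
that enrichment of the PDEG set recovers it at FDR 0.05 while neutral terms
stay flat.
"""

import numpy as np

from xdeg import RunConfig, SimulationConfig, run_pipeline
from xdeg.enrichment import enrichment_frame

config = RunConfig(
    sim=SimulationConfig(n_ortholog_pairs=2000, n_specific_a=300, n_specific_b=300),
    orf_n_shuffles=5, orf_max_records=50,
    seed=5,
)
res = run_pipeline(config)

rows = res.species_a.enrichment
print(f"species A: {res.species_a.pdeg.total} PDEG contigs tested against "
      f"{res.summary['n_contigs_a']} contigs; {len(rows)} terms")
print(enrichment_frame(rows).head(5).to_string(index=False))
sig = [r.term for r in rows if r.significant]
print(f"significant at q <= 0.05: {sig}")
print("-> T_SPECIFIC is the planted marker of species-specific genes; finding")
print("   only it significant shows the test separates signal from the flat")
print("   background terms.")
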