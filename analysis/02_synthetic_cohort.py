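#!/usr/bin/env python
"""Run the neoantigen cascade end-to-end on a synthetic patient.

Generates a cohort with the default study-like conditions (84 non-silent
mutations, half clonal, purity 0.6 at 200x depth, ~3/4 of mutated genes
unexpressed), runs the full cascade with the packaged stub predictor, and
compares the clonal/subclonal calls against the planted truth. The funnel
narrows sharply at the binding and expression stages, as in real tumors, and
clonality labels recover with >= 95% concordance.

Writes results/synthetic_candidates.tsv, results/synthetic_funnel.json and
results/synthetic_burden.json.
"""

import warnings
from pathlib import Path

from neoclone.burden import estimate_ccf
from neoclone.config import PipelineConfig
from neoclone.pipeline import run_neoantigen_pipeline
from neoclone.selection import write_candidate_table
from neoclone.simulate import SimulationConfig, simulate_genomics

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 17) -> None:
    cfg = SimulationConfig(seed=seed)
    g = simulate_genomics(cfg)
    pconf = PipelineConfig(purity=cfg.purity)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ccf clipping at vaf noise is expected
        candidates, funnel, burden = run_neoantigen_pipeline(
            g.proteins, g.variants, g.expression, pconf
        )
        hits = sum(
            estimate_ccf(v.vaf, cfg.purity).clonal == row.clonal_true
            for v, row in zip(g.variants, g.truth.itertuples())
        )

    RESULTS.mkdir(exist_ok=True)
    write_candidate_table(candidates, RESULTS / "synthetic_candidates.tsv")
    funnel.to_json(RESULTS / "synthetic_funnel.json")
    burden.to_json(RESULTS / "synthetic_burden.json")

    print(f"mutations                    : {funnel.n_nonsynonymous}")
    print(f"peptide pairs enumerated     : {funnel.n_peptide_pairs}")
    print(f"binder peptides (<500 nM)    : {funnel.n_binder_peptides} "
          f"({funnel.n_binder_mutations} mutations)")
    print(f"expressed genes among binders: {funnel.n_expressed_genes}")
    print(f"selected candidate peptides  : {funnel.n_candidate_peptides}")
    print(f"distinct neoantigens         : {funnel.n_neoantigens}")
    print(f"TMB                          : {burden.tmb:.2f} muts/Mb ({burden.tmb_class})")
    print(f"TNB                          : {burden.tnb:.2f} neos/Mb "
          f"({'high' if burden.tnb_high else 'not high'})")
    print(f"clonality concordance        : {hits}/{cfg.n_variants} "
          f"({hits / cfg.n_variants:.1%})")


if __name__ == "__main__":
    main()
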