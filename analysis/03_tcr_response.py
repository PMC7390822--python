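#!/usr/bin/env python
"""Detect and track neoantigen-specific T-cell clones on a synthetic cohort.

Generates longitudinal blood repertoires plus a mutant/wild-type peptide
stimulation pair with 25 planted responder clones (18 persistent
high-frequency blood clones, 7 appearing only after treatment start), runs
the one-sided Fisher expansion screen (OR > 10, p < 0.01) and the
longitudinal tracker, and checks recovery of the planted split.

Writes results/tcr_significant.tsv, results/tcr_tracks.tsv and per-sample
V-J usage matrices under results/.
"""

from pathlib import Path

from neoclone.pipeline import run_tcr_pipeline
from neoclone.repertoire import (
    write_clone_tracks,
    write_significance_table,
    write_vj_long,
)
from neoclone.simulate import SimulationConfig, simulate_repertoires

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 17) -> None:
    cfg = SimulationConfig(seed=seed)
    r = simulate_repertoires(cfg)
    report = run_tcr_pipeline(r.blood_samples, r.mutant_stim, r.wt_stim)

    RESULTS.mkdir(exist_ok=True)
    write_significance_table(report.significant, RESULTS / "tcr_significant.tsv")
    write_clone_tracks(report.tracks, RESULTS / "tcr_tracks.tsv")
    for label, matrix in report.vj_matrices.items():
        write_vj_long(matrix, RESULTS / f"vj_usage_{label}.tsv")

    truth_keys = {(row.cdr3nt, row.v, row.j) for row in r.truth.itertuples()}
    found = {res.clone_key for res in report.significant}
    print(f"clones flagged significant   : {report.n_significant}")
    print(f"planted responders recovered : {len(found & truth_keys)}/{len(truth_keys)}")
    print(f"persistent high-frequency    : {report.n_persistent}")
    print(f"post-treatment-only          : {report.n_post_only}")


if __name__ == "__main__":
    main()
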