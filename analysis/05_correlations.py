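#!/usr/bin/env python
"""Cross-sectional screen: metabolic variables vs clinical covariates.

Mirrors the translational step: variables selected for diet response in the
mouse arm are examined against metabolic-syndrome covariates in the human
cohort with pairwise-complete Pearson correlations. p-values are NOT
corrected for multiple comparisons (exploratory screen).
"""

import warnings
from pathlib import Path

import pandas as pd

from metabfuse.pipeline import RunConfig, run_pipeline

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    warnings.simplefilter("ignore")
    outdir = Path("scratch/runs/human")
    if not (outdir / "correlations.csv").exists():
        run_pipeline(RunConfig(profile="human", seed=1, outdir=str(outdir)))
    corr = pd.read_csv(outdir / "correlations.csv")
    # keep the strongest cells in results; the full matrix stays in the run dir
    top = (
        corr.dropna()
        .assign(abs_r=lambda d: d["r"].abs())
        .sort_values("abs_r", ascending=False)
        .head(200)
        .drop(columns="abs_r")
    )
    top.round(5).to_csv(RESULTS / "correlations_human_top200.csv", index=False)
    print("NOTE: exploratory screen; p-values are not corrected for multiplicity")
    strongest = (
        corr.dropna()
        .assign(abs_r=lambda d: d["r"].abs())
        .sort_values("abs_r", ascending=False)
        .head(10)
    )
    print("strongest metabolite-covariate correlations (human cohort):")
    print(strongest[["variable", "covariate", "r", "p", "n"]].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
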