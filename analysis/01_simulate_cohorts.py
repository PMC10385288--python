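#!/usr/bin/env python
"""Generate the two synthetic cohorts and summarize what was planted.

Builds the mouse-style 2-diet x 2-time cohort (n=8/arm) and the human-style
23-vs-23 binary cohort with paired NMR spectra and LC-MS injection runs.
Full spectra go under scratch/ (they are large); the design summary and
true concentrations go under results/.
"""

import json
from pathlib import Path

import pandas as pd

from metabfuse.nmr import write_spectrum_csv
from metabfuse.pipeline import RunConfig, simulate_dataset

RESULTS = Path("results")
SCRATCH = Path("scratch/cohorts")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for profile in ("mouse", "human"):
        cfg = RunConfig(profile=profile, seed=1)
        data = simulate_dataset(cfg)
        truth = data["truth"]
        out = SCRATCH / profile
        (out / "spectra").mkdir(parents=True, exist_ok=True)
        for s in data["spectra"]:
            write_spectrum_csv(s, out / "spectra" / f"{s.sample_id}.csv")
        data["ms_table"].to_csv(out / "ms_raw.csv", index=False)
        truth.metadata.to_csv(RESULTS / f"metadata_{profile}.csv")
        truth.concentrations.round(5).to_csv(RESULTS / f"true_concentrations_{profile}.csv")
        if data["clinical"] is not None:
            data["clinical"].round(4).to_csv(RESULTS / "clinical_human.csv")
        for m, (factor, eff) in truth.affected.items():
            rows.append(
                {
                    "profile": profile,
                    "metabolite": m,
                    "factor": factor,
                    "log_fold_effect": eff,
                    "block": truth.effects.block_of(m),
                }
            )
        print(
            f"{profile}: {len(truth.concentrations)} samples, "
            f"{truth.concentrations.shape[1]} metabolites, "
            f"{len(truth.affected)} planted responders, "
            f"{len(data['spectra'])} spectra + {len(data['ms_table'])} MS injections"
        )
    planted = pd.DataFrame(rows)
    planted.to_csv(RESULTS / "planted_effects.csv", index=False)
    print(f"planted-effect table -> {RESULTS/'planted_effects.csv'}")


if __name__ == "__main__":
    main()
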