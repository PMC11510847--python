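"""Compare actual and model-predicted sRPE across tournament game numbers.

Builds the long actual/predicted table from the fitted workload model, runs
the two-factor ANOVA (game number x sRPE type, athlete blocking stratum),
the Tukey post hoc on game number and the Holm-adjusted paired
actual-vs-predicted tests per game, and writes the tables plus a plain-text
summary under `results/evaluation/`.
"""

from pathlib import Path

from sevensload.config import RunConfig
from sevensload.features import StudyDataset
from sevensload.pipeline import run_evaluate, run_fit

RECORDS = Path("results/study/records.csv")
OUT = Path("results/evaluation")


def main() -> None:
    if not RECORDS.exists():
        raise SystemExit(f"{RECORDS} not found -- run 01_simulate_study.py first")
    config = RunConfig(seed=1)
    dataset = StudyDataset.from_csv(RECORDS)
    fit = run_fit(config, dataset, OUT)
    reports = run_evaluate(config, dataset, fit, OUT)
    print(reports["summary"])
    print(f"\ntables written to {OUT}/")


if __name__ == "__main__":
    main()
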