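"""Fit the mixed-effects workload model to the simulated study records.

sRPE is regressed on athlete mass, contact count, total distance, the
acceleration-type distance sums and their low/high-speed interaction cells,
with a random intercept per athlete (REML). Writes the coefficient table,
the fit report JSON and both adjusted-R^2 variants under `results/fit/`,
and prints the significant terms with their signs.
"""

from pathlib import Path

from sevensload.config import RunConfig
from sevensload.features import StudyDataset
from sevensload.pipeline import run_fit

RECORDS = Path("results/study/records.csv")
OUT = Path("results/fit")


def main() -> None:
    if not RECORDS.exists():
        raise SystemExit(f"{RECORDS} not found -- run 01_simulate_study.py first")
    config = RunConfig(seed=1)
    dataset = StudyDataset.from_csv(RECORDS)
    fit = run_fit(config, dataset, OUT)
    table = fit.coefficients
    print(f"fitted {fit.n_obs} records, {fit.n_athletes} athletes; "
          f"sigma_u = {fit.sigma_u_hat:.2f} au, sigma_e = {fit.sigma_e_hat:.2f} au")
    sig = table[table["p"] < 0.01]
    print("significant terms (p < 0.01):")
    for term, row in sig.iterrows():
        print(f"  {term:10} {row['estimate']:+9.4f}  t = {row['t']:6.2f}")
    ns = [t for t in table.index if t not in sig.index]
    print(f"non-significant: {', '.join(ns)}")
    print(f"reports written to {OUT}/")


if __name__ == "__main__":
    main()
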