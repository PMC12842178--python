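"""Planted-gene recovery of the CAST burden scan across 20 simulations.

For each seed: 60 cases vs 1246 controls, 50 genes, 4 genes planted with
exactly six case carriers and zero control carriers.  Reports how often all
planted genes are flagged at BH-FDR 0.5% by both the right-tailed Fisher
test and the Firth regression, and how often no unplanted gene is flagged.
Writes per-seed results to results/burden_scan/.
"""

import warnings
from pathlib import Path

import pandas as pd

from ndd_burden import SimulationConfig, run_pipeline, simulate_cohort
from ndd_burden.cast_burden import results_to_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "burden_scan"


def main(n_seeds: int = 20) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    example = None
    for seed in range(1, n_seeds + 1):
        cfg = SimulationConfig(
            n_cases=60, n_controls=1246, n_genes=50, n_enriched_genes=4,
            enriched_case_carrier_count=6, enriched_control_carrier_count=0,
            seed=seed,
        )
        samples, sites, geno, truth = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, _ = run_pipeline(sites, geno, samples)
        both = {r.gene for r in results if r.q_fisher <= 0.005 and r.q_firth <= 0.005}
        either = {r.gene for r in results if r.q_fisher <= 0.005 or r.q_firth <= 0.005}
        rows.append({
            "seed": seed,
            "n_tested": len(results),
            "all_planted_recovered": truth <= both,
            "n_false_flags": len(either - truth),
        })
        if example is None:
            example = results_to_frame(results)
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "per_seed_recovery.tsv", sep="\t", index=False)
    example.to_csv(OUT / "example_scan_seed1.tsv", sep="\t", index=False)

    rec = summary["all_planted_recovered"].mean()
    clean = (summary["n_false_flags"] == 0).mean()
    print(f"{n_seeds} simulations: all 4 planted genes flagged by both tests in "
          f"{rec:.0%} of seeds; no false flag in {clean:.0%} of seeds")
    print("example scan (seed 1), significant genes:")
    sig = example[example["q_firth"] <= 0.005]
    print(sig[["gene", "n_case_carriers", "n_control_carriers",
               "fisher_p", "firth_or", "firth_p", "q_fisher", "q_firth"]].to_string(index=False))
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
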