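#!/usr/bin/env python
"""γ/δ ratio statistics: rank-sum on per-recording summaries, bootstrap z.

The ratio of normalized γ (30–80 Hz) to normalized δ (1–4 Hz) power of
each preictal discharge indexes how strongly synaptic volleys recruit
local firing.  Per-recording means/medians are compared by rank-sum;
the pooled per-event datasets are compared by bootstrap resampling of
the mean (10,000 resamples) with Gaussian-fit SEMs and a z-score.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ictalfp.cohortstudy import run_cohort_study
from ictalfp.stats import bootstrap_mean, bootstrap_z_comparison, ranksum_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--bootstrap", type=int, default=10_000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = run_cohort_study(seed=args.seed, n_bootstrap=args.bootstrap)
    summary = study["summary"]
    pooled = study["pooled_ratios"]

    report = {}
    for stat in ("mean_gamma_delta_ratio", "median_gamma_delta_ratio"):
        a = summary.loc[summary.group == "WT", stat].dropna().to_numpy()
        b = summary.loc[summary.group == "KO", stat].dropna().to_numpy()
        _, p = ranksum_test(a, b)
        report[stat] = {
            "wt_median": float(np.median(a)),
            "ko_median": float(np.median(b)),
            "p_ranksum": p,
        }

    res_wt = bootstrap_mean(pooled["WT"], args.bootstrap, seed=args.seed * 2 + 1)
    res_ko = bootstrap_mean(pooled["KO"], args.bootstrap, seed=args.seed * 2 + 2)
    z, p_z = bootstrap_z_comparison(res_wt, res_ko)
    report["pooled_bootstrap"] = {
        "n_events_wt": int(pooled["WT"].size),
        "n_events_ko": int(pooled["KO"].size),
        "mean_wt": res_wt.mean_of_means,
        "mean_ko": res_ko.mean_of_means,
        "sem_wt": res_wt.sem_gaussian_fit,
        "sem_ko": res_ko.sem_gaussian_fit,
        "z": z,
        "p_two_sided": p_z,
        "n_resamples": args.bootstrap,
        "seed": args.seed,
    }

    path = args.out / "05_gamma_delta_ratio.json"
    path.write_text(json.dumps(report, indent=1))
    print(f"γ/δ ratio statistics -> {path}")
    for stat in ("mean_gamma_delta_ratio", "median_gamma_delta_ratio"):
        r = report[stat]
        print(
            f"  per-recording {stat.split('_')[0]}s: WT {r['wt_median']:.2f} vs "
            f"KO {r['ko_median']:.2f} (rank-sum p = {r['p_ranksum']:.2g})"
        )
    pb = report["pooled_bootstrap"]
    print(
        f"  pooled events ({pb['n_events_wt']} WT vs {pb['n_events_ko']} KO): "
        f"means {pb['mean_wt']:.2f} vs {pb['mean_ko']:.2f}, "
        f"bootstrap z = {pb['z']:.2f} (p = {pb['p_two_sided']:.2g})"
    )
    print(
        "  the knockout-like group shows the compressed γ/δ distribution "
        "configured in the generator."
    )


if __name__ == "__main__":
    main()
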