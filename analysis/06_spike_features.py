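#!/usr/bin/env python
"""Paired cell-attached firing during preictal vs interictal discharges.

Renders cell-attached traces whose firing follows each LFP recording's
ground-truth event schedule — the wild-type-like condition fires at a
higher within-event maximal rate than the knockout-like one — then
detects spikes (MAD threshold on a high-passed trace), assigns them to
the LFP-defined event windows, and averages counts, maximal rates and
half-widths per recording and event class.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ictalfp.events import classify_events
from ictalfp.spectral import RawEventInterval
from ictalfp.spikes import detect_spikes, spike_stats_by_class, spikes_per_event
from ictalfp.stats import ranksum_test
from ictalfp.synth import (
    FiringModel,
    generate_recording,
    generate_spike_trace,
    reduced_ko_config,
    reduced_wt_config,
)

#: firing conditions: the knockout-like group fires at a lower max rate
FIRING = {
    "WT": FiringModel(aps_per_event=8, max_rate_hz=150.0, noise_sd_uV=1.5),
    "KO": FiringModel(aps_per_event=8, max_rate_hz=60.0, noise_sd_uV=1.5),
}

SPIKE_FS = 10_000.0  # spike channels keep the fine time base


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-per-group", type=int, default=4)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for group, cfg_f in (("WT", reduced_wt_config), ("KO", reduced_ko_config)):
        for i in range(args.n_per_group):
            cfg = cfg_f(args.seed + i)
            _, gt = generate_recording(cfg)
            # spikes only fit inside windows long enough for the burst
            trace = generate_spike_trace(
                gt, FIRING[group], SPIKE_FS, seed=args.seed * 100 + i
            )
            train = detect_spikes(trace)
            intervals = [
                RawEventInterval(onset_s=a, offset_s=b, onset_bin=0,
                                 offset_bin=0, peak_z=5.0)
                for a, b in zip(gt.event_onsets_s, gt.event_offsets_s)
            ]
            events, _ = classify_events(intervals)
            stats = spikes_per_event(train, events)
            for cls, vals in spike_stats_by_class(stats).items():
                rows.append(
                    {"group": group, "recording": i, "class": cls, **vals}
                )
    df = pd.DataFrame(rows)
    path = args.out / "06_spike_stats.tsv"
    df.to_csv(path, sep="\t", index=False)
    print(f"per-recording spike statistics -> {path}")

    for cls in ("preictal", "interictal"):
        sub = df[df["class"] == cls]
        a = sub.loc[sub.group == "WT", "mean_max_rate_hz"]
        b = sub.loc[sub.group == "KO", "mean_max_rate_hz"]
        if len(a) >= 2 and len(b) >= 2:
            _, p = ranksum_test(a, b)
            print(
                f"  {cls}: max firing rate WT {a.mean():.0f} Hz vs "
                f"KO {b.mean():.0f} Hz (rank-sum p = {p:.2g})"
            )
    print(
        "  spike counts and half-widths are configured equal across groups "
        "and recover as such; only the maximal rate differs."
    )


if __name__ == "__main__":
    main()
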