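"""Multi-session place-cell statistics on a synthetic cohort.

Generates a chronic linear-track experiment (declining active-cell count,
shrinking place fields), runs the session pipeline (speed filter, rate
maps, per-session statistics normalized to day one), and regresses the
statistics on experience day.
"""

import numpy as np

import driftlab as dl

config = dl.SynthCohortConfig(n_animals=4, n_days=8, n_cells=60, duration=1500,
                              decline_rate=0.03, seed=7)
cohort = dl.generate_cohort(config)

days, stat, si = [], [], []
for animal, sessions in cohort.items():
    df = dl.session_statistics(sessions, mode="active_count")
    days.append(df.day.to_numpy())
    stat.append(df.stat_norm.to_numpy())
    si.append(df.si_norm.to_numpy())
days = np.concatenate(days)

act = dl.trend_regression(np.concatenate(stat), days)
sit = dl.trend_regression(np.concatenate(si), days)
print(f"active-cell count: slope {act.slope:+.4f}/day (p = {act.p_value:.2e}, n = {act.n})")
print(f"mean SI:           slope {sit.slope:+.4f}/day (p = {sit.p_value:.2e}, n = {sit.n})")
print(
    f"\nThe planted 3%/day silencing is recovered by the activity trend "
    f"({act.slope:+.3f} vs -0.030 planted), and the shrinking tuning widths "
    "show up as a positive spatial-information trend — the experimental "
    "signature of the directed-drift phase."
)
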