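"""Recover every decision threshold empirically from engine behaviour.

Bisection over two-scan synthetic series locates the exact fractional
change at which each engine's call flips (SD -> PD, SD -> PR, T2 stable
-> progressed), and grid/sweep searches recover the measurability
cutoffs and the iRANO timing windows. Recovering the printed values
end-to-end shows the engines implement the criteria as specified, with
ties counting as crossings.
"""

from ranocrit.boundaries import recover_all

units = {
    "pd_2d_increase_pct": "% (2D product increase -> PD)",
    "pd_vol_increase_pct": "% (CE volume increase -> preliminary PD)",
    "pr_vol_decrease_pct": "% (CE volume decrease -> preliminary PR)",
    "pr_2d_decrease_pct": "% (2D product decrease -> PR)",
    "measurable_2d_cutoff_cm": "cm (per-lesion 2D measurability)",
    "measurable_vol_cutoff_cm3": "cm^3 (total-volume measurability)",
    "t2_vol_increase_pct": "% (T2/FLAIR volume increase -> progression)",
    "irano_window_months": "months (confirmation window after immunotherapy)",
    "irano_confirm_gap_months": "months (minimum confirmation interval)",
}
for key, value in recover_all().items():
    print(f"{key:<28}{value:>8}  {units[key]}")
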