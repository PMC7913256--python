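"""Discordant-pair odds ratios from published exposure-classification counts.

The counts below are the two control-window analyses of a case-crossover
study of tricyclic antidepressants and hip fracture (continuous users,
non-users, intermittent users, recent stoppers).  Only the discordant cells
(intermittent / recent stopper) inform the odds ratio; the closed form
b/c with a Wald log-OR interval is the exact conditional-logistic result
for this 1:1 self-matched design.
"""

from crossvis import DiscordantCounts, odds_ratio

tables = [
    DiscordantCounts(3498, 2441, 127, 108, "CW1"),  # control window 101-150
    DiscordantCounts(3268, 2471, 150, 105, "CW2"),  # control window 151-200
]

for counts in tables:
    r = odds_ratio(counts)
    print(f"{counts.control_window_label}: "
          f"{counts.n_intermittent} intermittent vs {counts.n_recent_stopper} stoppers -> "
          f"OR {r.odds_ratio:.2f} (95% CI {r.ci_lower:.2f}-{r.ci_upper:.2f})")

# Prints OR 1.18 (0.91-1.52) for CW1 and OR 1.43 (1.11-1.83) for CW2: the
# nearer control window shows no association, the farther one an apparently
# significant risk — the discrepancy the misclassification assessment explains.
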