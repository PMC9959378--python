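"""Aggregate the packaged ten-user system-test rating table.

Ten users rated six aspects of the system on a 1-5 scale (1 = very bad,
5 = very good).  The report gives per-aspect means and the grand mean.
"""

from baropod import summarize_survey, table4_survey

summary = summarize_survey(table4_survey())
for aspect, mean in summary.aspect_means.items():
    print(f"{aspect:24s} {mean:.2f}")
print(f"{'overall':24s} {summary.overall_mean:.2f}")
print()
print("The weakest aspect is wearing comfort (battery bulk); everything")
print("else sits near the top of the scale.")
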