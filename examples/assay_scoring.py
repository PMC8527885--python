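"""Score a simulated crystal-violet biofilm-formation plate.

Simulates 15 strains x 8 replicate wells with 6 planted biofilm formers,
aggregates each strain's OD595/OD600 ratios and applies the former call
(aggregate ratio strictly above 5).
"""

from biofilmquant.assay import score_plate
from biofilmquant.simdata import gen_assay_plate

plate = gen_assay_plate(n_strains=15, n_replicates=8, former_fraction=0.4,
                        seed=7)
scores = score_plate(plate)
print(scores.round(2).to_string(index=False))
truth = plate.groupby("strain_id")["is_former_true"].first()
agree = (scores.set_index("strain_id")["is_former"] == truth).mean()
print(f"\n{int(scores['is_former'].sum())} of {len(scores)} strains called "
      f"biofilm formers (ratio > 5); agreement with planted labels: "
      f"{100 * agree:.0f}%")
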