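"""Work with the packaged 34-compound reference hit table.

Summarizes WT potency by drug class and recomputes the percent change of
activity between the wild-type and N62S-mutant cell lines.
"""

import mrgscreen as ms

df = ms.load_reference_hits()
library = ms.reference_hit_library()
b_wt = dict(zip(df["compound_id"], df["b_score_wt"]))

print(f"{len(df)} reference hits in {df['drug_class'].nunique()} classes\n")
for s in sorted(ms.class_summary(b_wt, library), key=lambda s: -s.mean_b):
    sd = f"+/- {s.sd_b:5.2f}" if s.sd_b is not None else ""
    print(f"  {s.drug_class:<40s} n={s.n:<3d} B = {s.mean_b:6.2f} {sd}")

imipramine = df[df["name"] == "Imipramine Hydrochloride"].iloc[0]
pct = ms.percent_change(imipramine["b_score_wt"], imipramine["b_score_mut"])
print(
    f"\nimipramine: B(WT) = {imipramine['b_score_wt']}, "
    f"B(N62S) = {imipramine['b_score_mut']}, change = {pct:.2f}%"
)
# A change near -100% means the N62S mutation removes essentially all of the
# compound's agonist activity; imipramine retains about half.
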