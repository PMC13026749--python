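"""A scaled-down factorial virtual study with the full measurement chain.

Techniques x experience groups x operators x screws, every screw simulated,
digitized, fitted, registered, measured and graded.  The summaries mirror
the validation analyses: Spearman correlations of coaxiality with the
component errors, senior-vs-junior Mann-Whitney comparisons, and breach
prevalence.  (The default design is 3 x 2 x 4 x 10 = 240 screws; this
example runs 3 x 2 x 2 x 5 = 60 to stay quick.)
"""

from pedscrew.phantom import StudyDesign, run_virtual_study

design = StudyDesign(operators_per_group=2, screws_per_operator_technique=5)
res = run_virtual_study(design, seed=11)
t = res.table

print(f"{len(t)} simulated insertions in {res.runtime_s:.1f} s")
print("\nper-technique means (ground truth):")
print(t.groupby("technique")[["ee_true", "et_true", "e_alpha_true", "C_true", "dpw_true"]]
      .mean().round(2).to_string())

s = res.summaries
print("\ncoaxiality correlations (pipeline estimates):")
for err in ("ee", "et", "e_alpha"):
    r = s[f"spearman_C_{err}"]
    print(f"  Spearman(C, {err:7s}) rho = {r['rho']:.2f} (p = {r['p']:.2g})")
print("\nsenior vs junior (Mann-Whitney, two-sided):")
for p in ("ee", "et", "e_alpha", "C", "dpw"):
    print(f"  {p:8s} p = {s['mw_senior_junior_' + p]['p_two_sided']:.3f}")
print(f"\nbreach prevalence (truth): {100 * s['breach_prevalence_true']:.1f}%  "
      f"(estimated: {100 * s['breach_prevalence_est']:.1f}%)")
print("\nestimated vs true Gertzbein grades (chain fidelity):")
print(s["gertzbein_crosstab"].to_dataframe().to_string())
print("\nCoaxiality tracks the target error closely (C = max(ee, et), and et")
print("usually dominates), while angular skill differences separate the groups.")
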