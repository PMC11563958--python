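"""Run a scaled-down burn-in and one evaluation scheme year by year.

The burn-in establishes a realistic base population by 40 years of
phenotypic selection (here shortened and shrunk for speed); the 2-year
within-cohort scheme then runs from that state, recycling parents on
GEBVs every second year of each cohort's life.
"""

from breedsim import (BurninConfig, GenomeSpec, SchemeConfig, TraitSpec,
                      genetic_gain, run_burnin, run_scheme)

genome = GenomeSpec(n_chromosomes=4, n_qtl=400, n_markers=160, n_founders=40)
burnin = BurninConfig(n_founders=40, n_crosses=30, progeny_per_cross=30,
                      lst_survivors_per_family=8, oyt_survivors=200,
                      stage2_size=20, n_parents=40, years=20,
                      training_size=100)
state = run_burnin(genome, TraitSpec(gei_variance=0.0), burnin, seed=5)
print(f"burn-in: base population of {state.base_pop.n} Stage-1 lines, "
      f"mean GV {state.burnin_records[-1]['mean_gv']:.2f}, "
      f"variance {state.burnin_records[-1]['var_gv']:.3f}")

cfg = SchemeConfig(scheme="2-year-wp", n_parents=20, n_crosses=15,
                   progeny_per_cross=40, mas_survivors_per_family=10,
                   est_size=60, stage2_size=10)
rows = run_scheme(state, cfg, years=10, seed=6)
print("year  mean_gv(centered)  variance  accuracy  criterion")
for r in rows:
    print(f"{r['year']:4d}  {r['mean_gv_centered']:17.3f}  {r['var_gv']:8.3f}"
          f"  {r['accuracy']:8.3f}  {r['criterion']}")
est = genetic_gain([r["mean_gv_centered"] for r in rows], horizon=10)
print(f"realized genetic gain (OLS slope, years 0-10): {est.slope:.3f} per year")
# The centered mean rises as recycling compounds; genetic variance erodes
# as favorable alleles move toward fixation.
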