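"""End-to-end smoke-scale study on one cell: Morris screening over all
nine model parameters, freezing, and a small Sobol' stage.

This runs real PDE solves at reduced scale (48^2 grid, r=3 Morris bases,
n=4 Saltelli samples), so it takes a few minutes; it demonstrates the
pipeline, not converged indices.
"""

from llps_gsa import StudyConfig, run_study

config = StudyConfig(grid_nx=48, grid_length=1.875, morris_r=3, sobol_n=4,
                     morris_tcap=10.0, ratios=("1:1",), qois=("time",),
                     seed=1, outdir="scratch/mini_study")
summary = run_study(config)

cell = summary.cell("time", "1:1")
print(f"retained parameters : {cell.retained}")
print(f"separation-time median {cell.distribution['median']:.0f} s, "
      f"{cell.distribution['percent_capped']:.0f}% capped")
print(f"simulations: {cell.n_morris_simulations} (screening) + "
      f"{cell.n_sobol_simulations} (Sobol')")
print()
print("Reports (CSV/JSON) are under scratch/mini_study/.")
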