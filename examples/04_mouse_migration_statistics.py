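"""A two-group in-silico study: per-mouse migration rates and a Welch test.

Simulates control and treated mice (different per-follicle melanocyte
rates), quantifies every field, pools counts into per-mouse migration
rates (melanocytes / follicles), and compares the groups with a two-tailed
Welch t test, reporting means ± SEM.
"""

from skinquant import FieldParams, RunConfig, run_pipeline
from skinquant.config import GroupSpec, PathsConfig, SimulationConfig

cfg = RunConfig(
    paths=PathsConfig(output_dir="scratch/example_run"),
    simulation=SimulationConfig(
        params=FieldParams(width_px=512, height_px=512, n_follicles=20),
        n_fields=10,
        groups=(GroupSpec("ctrl", 4, mcsc_rate=0.05),
                GroupSpec("treated", 4, mcsc_rate=0.20))),
    seed=11)

bundle = run_pipeline(cfg)
print(bundle.per_mouse[["mouse_id", "group", "total_follicles",
                        "total_mcsc", "migration_rate"]].to_string(index=False))
row = bundle.comparisons.iloc[0]
print(f"\nWelch t = {row.statistic:.3f}, p = {row.p:.4g}")
print(f"ctrl    {row.mean_a:.4f} ± {row.sem_a:.4f} (SEM, n={row.n_a})")
print(f"treated {row.mean_b:.4f} ± {row.sem_b:.4f} (SEM, n={row.n_b})")
# The per-mouse rates recover the configured per-follicle rates and the
# treated group separates from control at this effect size.
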