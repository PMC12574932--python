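"""Calibrate the generator to a reference landscape, then mass-produce
equivalent maps.

A reference landscape is generated from known parameters and profiled by
its number of arable patches and mean/SD patch area.  The genetic
algorithm then searches potential-space share, coverage and mean field
size for parameters whose landscapes match that profile (fitness 1 =
perfect match).  From the calibrated parameters any number of
"equivalent" maps can be drawn: alike in the optimized metrics, free in
everything else — the held-out metric quartiles show that freedom.
"""

from agroscape import GAConfig, GeneratorSetup, run_ga
from agroscape.calibration import generate_equivalents, landscape_profile, simulate_landscape

truth = GeneratorSetup(nrow=100, ncol=100)
truth.share = 0.6
truth.field_params.coverage = 0.7
truth.field_params.mean_size = 1.0

reference = landscape_profile(
    simulate_landscape(truth, 999), metrics=("np", "area_mn", "area_sd")
)
print("reference profile:", {k: round(v, 2) for k, v in reference.values.items()})

cfg = GAConfig(
    population=20,
    generations=30,
    seed=1,
    metric_subset=("np", "area_mn", "area_sd"),
    stop_at_fitness=0.9,
)
bounds = {"share": (0.3, 0.9), "coverage": (0.3, 0.95), "mean_size": (0.3, 3.0)}
best, trace = run_ga(reference, bounds, cfg, truth)
print(f"best fitness {trace[-1]:.3f} after {len(trace)} generations")
print("calibrated parameters:", {k: round(v, 3) for k, v in best.as_dict().items()})

maps, report = generate_equivalents(best, 20, seed=123, setup=truth,
                                    optimized_metrics=cfg.metric_subset)
print(f"\n{report['n_maps']} equivalent maps generated")
print("optimized metrics (quartiles across maps):")
for metric, q in report["optimized"].items():
    print(f"  {metric:<8} q1={q['q1']:.2f}  median={q['median']:.2f}  q3={q['q3']:.2f}")
print("held-out metrics (not optimized — the remaining freedom):")
for metric, q in report["held_out"].items():
    print(f"  {metric:<8} q1={q['q1']:.2f}  median={q['median']:.2f}  q3={q['q3']:.2f}")
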