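"""Micro-to-macro rate mapping at toy scale.

Scans the microscopic binding rate, fits kon_macro per point, fits the
Hill relation kon_macro(kon_micro), and derives the Collins-Kimball
scaling factors fs (on the diffusion-limited plateau) and fr (on the
reaction volume).  Takes a minute or two.
"""

from rlbind import SimulationConfig
from rlbind.experiments import ExperimentPlan, run_scan

base = SimulationConfig(
    variant="O-SOL", koff_micro=0.1,
    D_R=10.0, D_L=10.0, N_R_phys=100, N_L_phys=100, s=1.0,
    R_cell=0.15, R_env=1.9302, o_binding_radius=0.03, r_L=0.02,
    t_end=1.0, sample_interval=0.02, seed=11)

plan = ExperimentPlan(base_config=base,
                      kon_micro_grid=(1e4, 5e4, 1e5, 1e6),
                      replicates=2)
frame, summaries = run_scan(plan)
print(frame[["kon_micro", "kon_macro_hat", "sse"]].to_string(index=False))
for key, s in summaries.items():
    print(f"\n{key}: Hill a = {s['a']:.3f} µm³/s, b = {s['b']:.3g} 1/s")
    print(f"  ks = {s['ks']:.3f} µm³/s, Vr = {s['Vr']:.3g} µm³")
    print(f"  scaling factors fs = {s['fs']:.2f}, fr = {s['fr']:.2f}")
print("\nkon_macro saturates with kon_micro (Hill shape).  fs compares the")
print("fitted plateau with the Smoluchowski rate and fr the fitted slope")
print("with the ideal reaction volume: values near 1 recover ideal")
print("Collins-Kimball theory, with deviations from excluded volume and")
print("the finite diffusive step.")
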