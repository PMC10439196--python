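"""Equilibria and the conversion-rate regime map.

Evaluates the predator-free and coexistence equilibria of the reaction
system, the stability criterion at several conversion rates f, and the
Hopf-type threshold where the coexistence point loses stability.
"""

from stochprey import ModelParameters, equilibria, hopf_threshold_f

base = dict(a=1.1, b=0.7, c=2.1, m=1.0, d=0.5, sigma1=0.1, sigma2=0.1,
            eta1=0.01, eta2=0.01)

for f in (0.4, 0.7, 0.79, 0.80, 0.84):
    rep = equilibria(ModelParameters(f=f, **base))
    if rep.coexistence_feasible:
        P_star, Q_star = rep.coexistence_point
        print(f"f={f:.2f}: coexistence ({P_star:.4f}, {Q_star:.4f}) "
              f"criterion={rep.criterion_value:+.4f} -> {rep.classification}")
    else:
        print(f"f={f:.2f}: coexistence infeasible (predator-free regime, "
              f"prey -> a/b = {rep.prey_only_point[0]:.4f})")

f_star = hopf_threshold_f(ModelParameters(f=1.0, **base), (0.55, 1.5))
print(f"\nstability threshold f* = {f_star:.5f}")
print("below f*: coexistence is stable; above it the criterion turns negative"
      " and trajectories orbit the coexistence point.")
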