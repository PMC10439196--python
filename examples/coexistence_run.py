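"""Stable coexistence under multiplicative time noise.

Runs the positivity-preserving NSFD scheme at the stable-coexistence
parameter set (f=0.79) and compares the long-time space-averaged densities
with the closed-form coexistence point.
"""

from stochprey import equilibria, get_preset, run_preset, steady_state_distance

preset = get_preset("fig1_coexistence")
rep = equilibria(preset.params)
print(f"closed-form coexistence point: "
      f"({rep.coexistence_point[0]:.4f}, {rep.coexistence_point[1]:.4f})")

res = run_preset("fig1_coexistence", "nsfd", seed=1)
n_window = res.completed_steps // 10
print(f"run: {res.completed_steps} steps, negative entries: {res.negative_count}")
print(f"space-averaged densities over the final 10% of steps: "
      f"({res.mean_P[-n_window:].mean():.4f}, {res.mean_Q[-n_window:].mean():.4f})")
print(f"sup-node distance of windowed averages from the coexistence point: "
      f"{steady_state_distance(res, rep.coexistence_point):.4f}")
print("the simulated pair sits on the coexistence equilibrium up to the "
      "O(noise, step-size) bias of the scheme.")
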