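"""Geometry of the cusp: density, equilibria, bifurcation set, predictions.

Evaluates the stationary density exp(alpha*y + beta*y^2/2 - y^4/4)/psi at a
few control points, classifies them against the bifurcation set
27*alpha^2 < 4*beta^3, and shows the three fitted-value conventions.
"""

from cuspcat import ControlPoint, StateDensity, equilibria, predict_state

for alpha, beta in [(0.0, -1.0), (0.3, 1.5), (0.0, 2.0)]:
    pt = ControlPoint(alpha, beta)
    eq = equilibria(pt)
    d = StateDensity(alpha, beta)
    print(f"alpha={alpha:+.1f} beta={beta:+.1f}  region={eq.region:<9}"
          f" equilibria={tuple(round(r, 3) for r in eq.roots)}"
          f" psi={d.psi:.4f} mean={d.mean():+.4f} var={d.var():.4f}")
print("# 'bimodal' points lie inside the bifurcation set: two stable states")
print("# coexist there and the density has two humps; psi normalizes exp(U).")

pt = ControlPoint(0.1, 1.5)
print("\npredictions at (0.1, 1.5):")
print("  delay (came from y=-1):", round(predict_state(pt, "delay", previous_state=-1.0), 4))
print("  delay (came from y=+1):", round(predict_state(pt, "delay", previous_state=1.0), 4))
print("  maxwell (most probable):", round(predict_state(pt, "maxwell"), 4))
print("  mean (density average): ", round(predict_state(pt, "mean"), 4))
print("# the delay convention keeps the system on its current branch")
print("# (hysteresis); maxwell jumps to the globally most probable state.")
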