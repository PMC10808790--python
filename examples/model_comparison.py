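"""Compare the cusp model against the linear and logistic alternatives.

All three models are fitted by maximum likelihood on the same synthetic
study table (cusp-generated outcome) and compared by AIC/AICc/BIC and by
the linear-vs-cusp chi-square difference test.
"""

from cuspcat import compare_models, fit_diagnostics, generate_study, paper_preset
from cuspcat.pipeline import comparison_text
from cuspcat.regression import FitConfig

table = generate_study(paper_preset(seed=2))
comp = compare_models(table, FitConfig(n_starts=4, seed=0))
print(comparison_text({"comparison": comp.to_dict()}))
print("# the cusp-generated outcome is best explained by the cusp model:")
print("# every information criterion is smallest in its row, and the")
print("# chi-square difference test rejects the nested linear model.")
print("# best per criterion:", comp.best)

diag = fit_diagnostics(comp.fits["cusp"], table)
print(f"\npseudo-R2 = {diag.pseudo_r2:.3f}  (1 - Var(residual)/Var(state))")
print(f"rows inside the bifurcation set: {diag.n_in_bifurcation} of {table.n_analyzed}")
print(f"corr(residual, fitted) = {diag.resid_fitted_corr:.3f}  "
      "# a slight negative trend is expected under the delay convention")
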