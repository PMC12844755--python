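"""MAP-Bayesian dose individualization from a TDM history.

A young patient with preserved renal function starts on the standard
600 mg protocol; the 24 h trough comes back low.  The example conditions the
population model on that measurement (MAP estimate of the individual
clearance and volume) and recommends the once-daily maintenance dose that
reaches the 15 mg/L steady-state target.
"""

from teicopk import (
    CovariateVector,
    DoseEvent,
    Observation,
    Subject,
    ThetaSet,
    individual_parameters,
)
from teicopk.estimation import PopulationModel
from teicopk.simulation import map_estimate, recommend_dose

# young patient, preserved renal function, low-normal body size
cov = CovariateVector.from_ibw(IBW=66.0, EGFR=130.0, AGE=35.0)
model = PopulationModel.published()
prior = individual_parameters(ThetaSet.final(), cov)
print(f"a priori (covariates only): CL {prior.CL:.2f} L/h, V {prior.V:.0f} L")
d0 = recommend_dose(prior, target_cmin=15.0, interval=24.0)
print(f"a priori dose for Cmin,ss >= 15 mg/L: {d0:.0f} mg QD")

# TDM: trough at 24 h measured at 4.1 mg/L (lower than typically predicted)
history = Subject(
    "patient-A",
    [DoseEvent(0.0, 600.0, 0.5), DoseEvent(12.0, 600.0, 0.5)],
    [Observation(24.0, 4.1)],
    cov,
)
post = map_estimate(history, model)
print(f"posterior (after 24 h trough of 4.1 mg/L): "
      f"CL {post.CL:.2f} L/h, V {post.V:.0f} L")
d1 = recommend_dose(post, target_cmin=15.0, interval=24.0)
print(f"individualized dose: {d1:.0f} mg QD")
print("-> the low trough pulls the individual clearance above its covariate")
print("   prediction, so the recommended maintenance dose increases.")
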