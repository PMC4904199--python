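"""Sobel mediation: does right-hemisphere alpha carry the light effect?

Runs the full pipeline on a reduced study (8 participants, for speed),
then tests whether the effect of high-vs-low light on left-hemifield
response times is mediated by right-hemisphere pre-target alpha.
"""

from alphalight.mediation import mediation_sobel
from alphalight.pipeline import PipelineConfig, run_study, screen_for_rt

cfg = PipelineConfig(n_participants=8, seed=11)
study, selections, _ = run_study(cfg)
screened, _ = screen_for_rt(study, cfg)
sub = screened[(screened.hemifield == "left")
               & screened.light_condition.isin(("low", "high"))]
res = mediation_sobel(sub)
print(res.summary())
# An 'inconsistent' mediation: light RAISES right-hemisphere alpha
# (a > 0) and alpha predicts SLOWER responses (b > 0), yet the direct
# effect c' of light on left-hemifield RT is negative (faster).
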