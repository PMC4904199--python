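"""Select attention-sensitive electrodes from a synthetic session.

Covert attention suppresses alpha contralateral to the attended
hemifield; per hemisphere the 4 of 8 parieto-occipital candidates with
the most negative contralateral-minus-ipsilateral desynchronisation are
chosen. The generator plants the truth: full projection weight on four
electrodes per hemisphere, half weight on the rest.
"""

from alphalight import alphapower
from alphalight.electrodes import select_electrodes
from alphalight.montage import CANDIDATES
from alphalight.synth import (GeneratorParams, ScheduleConfig, SessionSpec,
                              make_schedule, simulate_session)

params = GeneratorParams()
schedule = make_schedule(ScheduleConfig(n_blocks=3), seed=1)
spec = SessionSpec(participant_id="P01", light_condition="medium",
                   condition_order=1, seed=5, subject_seed=5)
epochs, trials = simulate_session(spec, params, schedule)

filt = alphapower.bandpass_alpha(alphapower.baseline_epochs(epochs))
series = alphapower.alpha_envelope(filt)
desync = alphapower.posttarget_desync(
    series, trials, CANDIDATES["left"] + CANDIDATES["right"])
print(desync.sort_values("difference").head(8).round(3).to_string())

sel = select_electrodes(desync, session_id=spec.session_id)
for hemi in ("left", "right"):
    planted = (params.true_electrodes_left if hemi == "left"
               else params.true_electrodes_right)
    print(f"{hemi}: chosen {sorted(sel.chosen[hemi])}, "
          f"planted {sorted(planted)}")
# The most negative differences should sit on the planted electrodes.
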