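"""Generate a synthetic multimodal vigilance session and inspect its labels.

A latent vigilance state drifts as an AR(1) process; both feature streams and
the eye-event rates are driven by it, so PERCLOS (the fraction of blink +
closure events) tracks the latent state.
"""

import numpy as np

from dcra import SyntheticConfig, generate_session

config = SyntheticConfig(n_epochs=200, seed=42)
session = generate_session(config)

print(f"modality E features: {session.features_e.shape}  (epochs x T x dims)")
print(f"modality O features: {session.features_o.shape}")
print(f"PERCLOS range: [{session.perclos.min():.3f}, {session.perclos.max():.3f}]"
      f", mean {session.perclos.mean():.3f}")
r = np.corrcoef(session.latent, session.perclos)[0, 1]
print(f"corr(latent vigilance state, PERCLOS) = {r:.3f}")
ev = session.events[0]
print(f"first epoch events: blink={ev.blink} fixation={ev.fixation} "
      f"saccade={ev.saccade} closure={ev.clos}")
# PERCLOS near 1 means the eyes were mostly closing/blinking (drowsy);
# a high latent-PERCLOS correlation confirms the label tracks the state.
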