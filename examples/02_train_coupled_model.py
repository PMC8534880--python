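"""Train the coupled recurrent auto-encoder and predict PERCLOS.

Trains with coupling weight alpha = 0.4 (joint loss:
(1-alpha)(L_E + L_O) + alpha * S), fits the linear head on the fused
codes, and reports in-session RMSE / PCC.
"""

from dcra import (LabeledSession, SyntheticConfig, TrainConfig, fit_head,
                  generate_session, pcc, predict_perclos, rmse,
                  standardize_session, train_dcra)

session = generate_session(SyntheticConfig(n_epochs=200, seed=1))
ze, _ = standardize_session(session.features_e, session.features_e)
zo, _ = standardize_session(session.features_o, session.features_o)
std = LabeledSession(ze, zo, session.events, session.perclos)

config = TrainConfig(alpha=0.4, fine_tune_epochs=20, pretrain_steps=40, seed=1)
model, trace = train_dcra(std, config)
print(f"joint loss: {trace[0].L_total:.1f} -> {trace[-1].L_total:.1f} "
      f"over {len(trace)} steps")
print(f"final breakdown: L_E={trace[-1].L_E:.1f} L_O={trace[-1].L_O:.1f} "
      f"S={trace[-1].S_coupling:.2f}")

fit_head(model, ze, zo, session.perclos)
pred = predict_perclos(model, ze, zo)
print(f"in-session rmse={rmse(session.perclos, pred):.4f} "
      f"pcc={pcc(session.perclos, pred):.4f}")
# The coupling term S shrinks during training: the two modality codes are
# pulled toward a shared representation of the latent vigilance state.
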