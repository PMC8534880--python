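# Methods

This note documents the model, the synthetic data that exercises it, the
numerical choices, and what the bundled experiments do and do not show.

## The model

Two feature streams describe the same person: an EEG-like stream (default 36
features per time step) reflecting cortical state, and an EOG-like stream
(default 25 features) reflecting eye activity. Each stream is summarized per
epoch as a short sequence (T = 8 steps by default) and carries a continuous
vigilance label, PERCLOS — the fraction of eye-tracker events in an epoch that
are blinks or closures:

    PERCLOS = (blink + CLOS) / (blink + fixation + saccade + CLOS).

Each modality has a deep recurrent auto-encoder (DRA): a three-layer GRU
encoder (d -> d -> 20 -> 16 units), a linear projection to a 10-unit coupling
code, and a mirrored three-layer GRU decoder that receives the code repeated
at every time step and reconstructs the input sequence. The GRU cell is

    z_t = sigma(W_xz' x_t + W_hz' h_{t-1} + b_z)
    r_t = sigma(W_xr' x_t + W_hr' h_{t-1} + b_r)
    g_t = tanh (W_xg' x_t + W_hg'(r_t * h_{t-1}) + b_g)
    h_t = z_t * h_{t-1} + (1 - z_t) * g_t

with the update gate multiplying the *previous* state. Many libraries use the
opposite convention (z gating the candidate); this package implements the
form above literally, and the test suite pins it against a scalar-by-scalar
oracle.

The coupled model (DCRA) ties the two DRAs through the joint loss

    L = (1 - alpha) * (L_E + L_O) + alpha * S,

where L_E and L_O are squared-error reconstruction losses (squared Frobenius
norm per epoch, averaged over the batch) and S is the cross-modal coupling
loss between the two codes f_E and f_O, averaged over the batch:

* DCRA_E (Euclidean): S = ||f_E - f_O||^2.
* DCRA_M (learned metric): S = (f_E - f_O)' M (f_E - f_O) with a PSD matrix M
  learned beforehand by PGDM and frozen during network training.

alpha = 0 decouples the model into two independent auto-encoders (the test
suite verifies step-for-step equivalence with independent runs); alpha = 1
drops reconstruction entirely. The cross-modal term is implemented as a
squared Mahalanobis *distance* between the codes: a bilinear form f_E' M f_O
is not a distance and is unbounded below, so it cannot serve as a loss; the
bilinear form is nevertheless available behind `coupling_form="bilinear"` for
comparison.

PERCLOS predictions come from an affine least-squares head on the
concatenated codes [f_E ; f_O] (20 values), fitted on training folds only and
clipped to [0, 1]. The head falls back to ridge (penalty 1e-3) when the fit
is under-determined. A linear head is the smallest assumption: anything the
codes expose linearly is credited to the representation, not to the readout.

## Metric learning (PGDM)

PGDM learns M from same-class pairs S and different-class pairs D:

    min_M sum_S ||x_i - x_j||_M^2   s.t.  sum_D ||x_i - x_j||_M >= 1,  M PSD,

optimized through the unconstrained surrogate
g(M) = sum_S d_M^2 - log(sum_D d_M) by projected gradient descent: gradient
step, symmetrize, clip negative eigenvalues to zero. Two robustness measures:
the step size is halved whenever a proposal would increase g (so the accepted
loss trace is non-increasing), and each proposal is also offered the exact
minimizer along its own scale direction (g(cM) is minimized at
c* = 1/(2 sum_S d_M^2), in closed form), which prevents the badly scaled
first iterations that plain projected descent suffers when the S-term
dominates. After convergence M is rescaled to meet the D-constraint.

Class labels for pair construction come from discretized PERCLOS with cut
points (0.35, 0.70) — the usual awake / tired / drowsy convention. The metric
is learned from the coupling codes of the two *single-modality*
auto-encoders, pooled as samples in the shared 10-dimensional code space (one
label per epoch, used for both modalities' codes), as a separate preparatory
step.

The metric enters the coupling loss at the scale the PGDM program fixes
(through its D-constraint), with no further normalization. That scale is
typically much smaller than the identity's, so at equal alpha the
learned-metric coupling is a gentler, more targeted pressure than the
Euclidean one: it nudges the codes to agree along the class-relevant
directions PGDM found, instead of pulling the full code vectors together.

## Synthetic sessions

The generator emulates the structure of simulated-driving vigilance data:

* A latent vigilance-loss state v(t) in [0, 1]: an AR(1) process
  (coefficient 0.95, innovation sd 0.3) squashed by a logistic. The AR
  coefficient gives a correlation time of ~20 epochs — slow drift, as
  vigilance drifts over minutes.
* Eye-event counts per epoch: Poisson draws with log-linear rates in v.
  Blink and closure rates rise with v, fixation and saccade rates fall, so
  PERCLOS increases with v (rank correlation checked in the tests). Rate
  intercepts are set so epochs contain ~30-150 events, which keeps the
  Poisson noise in PERCLOS small (corr(v, PERCLOS) ~ 0.95).
* Features: modality m observes lambda_m * v(t) (fixed loadings, drawn once
  per session) plus a modality-specific AR(1) component (coefficient 0.8,
  scale 0.3) and white Gaussian noise (sd 0.3) per time step.

The defaults were calibrated once so that a *single-modality* linear readout
of the features reaches held-out RMSE ~ 0.10 / PCC ~ 0.75 — the performance
regime reported for single-modality recurrent auto-encoders on real
simulated-driving data — and were not revisited afterwards.

What the generator does not emulate: real EEG spectral structure, artifacts,
inter-subject variability, non-stationary noise, or any nonlinear
latent-to-feature map. Passing fusion tests therefore show that the coupled
training behaves as designed when its assumptions hold (a genuinely shared
latent process, linear loadings, independent modality noise); they do not
certify performance on real recordings.

## Training procedure

1. Greedy layer-wise pretraining of each encoder: layer k is trained as a
   shallow recurrent auto-encoder (the GRU layer plus a throwaway
   per-timestep affine readout reconstructing the layer's input sequence),
   consuming the frozen hidden sequence of layer k-1. Decoder layers start
   from random initialization.
2. Joint fine-tuning of everything under the joint loss with Adam
   (lr 0.001, batch 32), batch normalization after encoder layers 2-3 and
   decoder layers 1-2 (positions 2, 3, 5, 6 of the seven-layer stack),
   ReLU activations on hidden layers and Sigmoid on the output layer.
   Early stopping on relative epoch-mean loss change < 1e-5 over 5 epochs,
   within a fixed epoch budget.

Per-layer activations are applied to the hidden-state sequence a layer emits
to its successor; the gate equations themselves always use sigma/tanh as
printed above. Batch norm operates per feature over (batch x time) and uses
running statistics at inference. Initialization is uniform scaled by fan-in
from a named seed stream; one global seed fans out to named sub-seeds
(datagen, per-modality init, pretraining, batching, pair sampling) so single-
modality and coupled runs are step-for-step comparable.

Note one deliberate tension kept from the reference parameterization: inputs
are z-scored but the output layer is a Sigmoid, so reconstructions live in
(0, 1) and cannot match negative inputs exactly. Reconstruction error
therefore saturates above zero; this does not affect prediction, which reads
the codes, not the reconstructions.

## Evaluation machinery

RMSE and Pearson correlation, five-fold cross-validation with *contiguous*
time-block folds (shuffled folds would leak temporally adjacent epochs across
the split; the sessions are time series), standardization and head fitting on
training folds only. Model comparison across datasets: per-dataset ranks
(average ranks on ties), Friedman chi-square
chi2_F = 12/(N k (k+1)) sum_j R_j^2 - 3N(k+1), and the Nemenyi critical
difference CD = q_alpha sqrt(k(k+1)/(6N)) with a built-in q table for
alpha = 0.05, k <= 10. The critical-difference diagram marks each algorithm's
mean rank with a CD-wide segment; non-overlap means significance.

## The fusion study

`dcra.experiments.fusion_experiment` runs, per seed, a 3-fold cross-validated
comparison on a 240-epoch synthetic session: a decoupled run (alpha = 0,
which doubles as the two single-modality baselines), then Euclidean and
learned-metric coupled runs at alpha in {0.4, 1}, with the PGDM metric fitted
per fold from the alpha = 0 codes. Fine-tuning uses 25 epochs and pretraining
40 steps per layer — deliberately compact problem sizes chosen as the
package's default study scale; the qualitative orderings, not absolute
errors, are the object of interest. It reports:

* held-out RMSE per coupling weight for both variants,
* mean held-out Euclidean code distance ||f_E - f_O|| per coupling weight,
  measured on the Euclidean-coupling runs (that distance is the very loss
  their coupling term minimizes),
* single-modality baselines from the alpha = 0 model.

Expected pattern, which the acceptance tests assert over five seeds: code
distance falls as alpha rises; the fused learned-metric model at alpha = 0.4
beats both single-modality baselines; and alpha = 0.4 gives lower
cross-validated RMSE than both extremes. The Euclidean coupling reliably
shrinks code distance but tends *not* to improve prediction in this
synthetic setting: pulling codes together in the raw code space mixes each
modality's code noise into the other, correlating errors that fusion would
otherwise average away. The learned metric counteracts exactly this — PGDM
concentrates M on label-relevant code directions, so the coupling only
enforces agreement where the two modalities genuinely share information.
This mirrors the reported advantage of the metric variant over the
Euclidean one.

## Known limitations

* The GRU networks are trained by a small numpy autodiff core; problem sizes
  are desk-scale (hundreds of epochs, not hours of recordings).
* The Friedman chi-square recomputed from the printed comparison-study ranks
  is 21.23; the study itself reports 20.805 (and a critical value whose
  degrees of freedom do not match k-1 = 5). The package reports what the
  printed formula and ranks give.
* PGDM is convex but the projected-gradient optimizer is first-order; very
  ill-conditioned pair sets may need more iterations than the default 200.
* The alpha sweep's interior-vs-extremes ordering is a stochastic trend on
  synthetic data, not a guarantee per seed.
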