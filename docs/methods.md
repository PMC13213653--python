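# Methods

`dyadeeg` identifies rare critical events — fortress kills and each
player's deaths — in a two-player cooperative task from the two players'
EEG. The pipeline has four scientific stages: a generative model of the
task and its evoked responses (the synthetic study), single-trial
class-conditional modelling of tick windows, multiplicative fusion of the
two players' evidence, and duration-aware semi-Markov placement of events
in time. This note documents the models, their assumptions, the defaults
and why, and what the synthetic results do and do not establish.

## The task and its timebase

Games are 3 minutes sampled at the 60 Hz game tick rate (10,800 ticks);
EEG is analyzed at the same rate, so one tick = 1/60 s. Three event
classes occur: `Kill` (the fortress is destroyed), `ShooterDeath`, and
`BaitDeath`; every other tick is `Null`. Events are extremely rare —
about 14 kills and 0.7 deaths per role per game, roughly 0.14% of ticks.

## Synthetic study generator (`dyadeeg.simulate`)

The generator reproduces the statistical structure the analysis relies
on, not the game physics.

**Event timing.** Inter-event intervals are shifted gamma distributions
(`DurationModel`): density zero at and below a minimum duration, gamma
mass above it. Defaults (ticks): start→first-kill mean 594 (9.9 s),
shape 3, shift 180; kill→kill mean 738 (12.3 s), shape 3, shift 240 —
the first interval is shorter because the ships start in position, while
between kills they must fly out and return. These means reproduce ~14
kills per 3-minute game. The gamma family is an assumption (the shapes
of empirical inter-kill histograms are unimodal with a hard minimum);
the family is configurable.

**Deaths.** Per role, the death count per game is Poisson(0.7), thinned
to at most one death per kill-bounded segment. A death's position within
its segment is drawn from the normalized product of a start-anchored
density (time since the previous kill, shift 60 ticks = 1 s minimum) and
an end-anchored density (time to the next kill, shift 60 ticks), both
gamma with mean 360 ticks, shape 2. Host segments are chosen with
probability proportional to their admissible density mass, so deaths
preferentially occur in long segments — matching the observation that
death-bearing segments are much longer than average. An optional
near-kill mode (off by default) places a configurable fraction of Bait
deaths a few ticks after a kill, emulating a shell already in flight
when the fortress dies.

**Evoked responses.** Every event adds a P300-like positive half-cosine
bump (width 0.3 s) to both players' EEG at full gain on the midline
electrodes FZ/CZ/PZ and 0.5 gain elsewhere. Amplitude (µV) and peak
latency (s) depend on role x event:

| role    | Kill      | ShooterDeath | BaitDeath  |
|---------|-----------|--------------|------------|
| Shooter | 6 @ 0.28  | 10 @ 0.33    | 6 @ 0.40   |
| Bait    | 4 @ 0.32  | 7 @ 0.38     | 11 @ 0.35  |

These defaults encode the qualitative structure of the observed
responses: each player responds most strongly to their own death;
Shooters are more positive than Baits after kills and Shooter deaths and
less positive after Bait deaths; kills are registered earliest by both
roles; each player registers their own death before their partner's.
The magnitudes are plausible P300 values against the 9 µV background
noise; the exact functional form (half-cosine) and topography (0.5
falloff) are modelling choices — real scalp fields and waveforms are
richer. Per event and player an independent Gaussian latency jitter
(SD 1 tick) is added.

**Noise.** White Gaussian noise, SD 9 µV, per electrode (AR(1) with
configurable coefficient available). Real EEG has 1/f structure,
oculomotor artifacts, and spatial correlation; none of these are
simulated, so passing tests show the *method* behaves as designed under
its own assumptions, not that real-data performance is guaranteed.

Everything is deterministic given a master seed (per-game child seeds are
spawned from it), and `generate_dataset` writes event logs (CSV + JSON
sidecar) and EEG (HDF5, bit-exact round trip; CSV available).

## Windowing and features (`preprocess`, `features`)

For classification, each electrode is z-scored over the whole game, and
each interior tick j gets the flattened 61-sample window j−30..j+30 for
every electrode (electrode-major layout, fixed across train/test; 19
electrodes → 1159 dimensions). Edge ticks have no vector; events there
are flagged and dropped from supervised sets. The ERP path keeps µV
units and stacks 61-sample event-locked epochs per class.

PCA reduces the vectors to the top `ceil(d/2)` components (1159 → 580;
a 64-electrode montage would give 3904 → 1952). The default fits the
PCA on vectors pooled from all games — unsupervised structure shared
across folds, mirroring the original analysis design; fitting on
training games only is a caller choice (pass training vectors). For
tractability the PCA and the class models are estimated from a per-game
stratified subsample: all event ticks plus a seeded cap of Null ticks
(defaults: 100/game for PCA, grown automatically if fewer than k+1
vectors result; 400/game for model fitting). Target games are always
scored on all interior ticks.

## Class-conditional models and fusion (`classify`)

Tick vectors in PCA space are modelled per class as multivariate normals
with class means and a single pooled covariance (linear-discriminant
structure; with 580 dimensions and thousands of training rows the pooled
covariance needs regularization, so it is shrunk toward its diagonal,
λ = 0.05 by default). Log-densities use a Cholesky factorization; with
the shared covariance any pairwise log-ratio is affine in the features.

Two training regimes: *within-team* (the pair's other games,
leave-one-game-out) and *between-team* (other pairs' games, same role;
leave-team-out). The target game never contributes to its own training
set. When a fold lacks an event class entirely (deaths are rare), the
missing class's training rows are borrowed from the other teams — never
from the target game; duration models fall back the same way.

The two players' per-tick conditional densities are fused
multiplicatively and renormalized over the four classes (log-space, via
log-sum-exp). The fusion is commutative, a uniform partner is neutral,
and fusing a source with itself squares and renormalizes likelihood
ratios. Threshold classification labels a tick A over B when the density
ratio strictly exceeds θ (ties to B, the Null-favoring convention); a
helper converts "posterior equality" into θ = prior(B)/prior(A) using
training-fold class frequencies.

## Event placement (`hsmm`, `durations`)

**Kills.** A placement of k kills at ticks t₁ < … < t_k scores

    Σ llr(t_m) + log f_start(t₁) + Σ log f_between(t_m − t_{m−1})
      + log S_between(T − t_k)

with the zero-kill placement scored log S_start(T). `llr` is the fused
Kill-vs-Null log-ratio (an odds-vs-all-classes emission is available);
f are the fitted duration densities and S_between the survival function
of the between-kill model — the final interval is censored because the
game ending is not a kill (censoring can be disabled). The exact
likelihood being maximized was an open design point; this objective is
the package's explicit reconstruction. A dynamic program over candidate
ticks solves it exactly in O(T × D_max); D_max defaults to the whole
game. Kills cannot be placed on edge ticks (no feature vectors there).
Duration models for a target game are fitted on the same team's other
games, pooling all other games when a team provides fewer than three
intervals; the shift defaults to the sample minimum minus one tick, and
spread-free samples fall back to a flagged narrow kernel.

**Deaths.** Segments between consecutive kills (including game start and
end) that contain exactly one death of a role are analyzed. The duration
prior over the segment is f_start(t) · f_end(L − t) normalized over
admissible ticks; the first and last 30 ticks (0.5 s) of a segment are
excluded so kill-adjacent EEG cannot masquerade as a death. The death is
placed at the argmax of log prior plus the fused between-team
death-vs-Null score (ties to the earlier tick). The prior-only baseline
places at the prior mode.

A note on a real failure mode: a strong death response projects
positively onto the Kill-vs-Null discriminant (the templates share
topography and overlap in time), so at high death rates death ticks can
out-score true kills for the kill placer. At the study's actual rates
(14 kills vs 0.7 deaths per game) the effect is minor; the
`emission="odds"` option penalizes death-attributed ticks but cannot
remove the ambiguity entirely, because a death observed a few ticks late
genuinely resembles a kill.

## Scoring (`score`, `roc`)

AUC is the exact Mann-Whitney rank statistic (ties 0.5); team-level
tables average per-team AUCs and attach a two-sided sign test (ties
excluded). The mismatch score averages (a) the mean distance from each
true event to its nearest prediction and (b) the mean distance from each
prediction to its nearest true event, distances capped at 100 ticks; an
empty prediction (or truth) set pins its component at the cap, and two
empty sets score 0 — the empty-set conventions are this package's
choice. `within_k` is the fraction of true events with a prediction
within k ticks (default 2 ticks ≈ 33 ms). Reconstruction ranking scores
every game's truth against every game's reconstruction and ranks the
own reconstruction (ties get mean rank; chance mean rank (G+1)/2).

## ERP summaries (`erp`)

The P300 window is 0.25–0.50 s post-event: samples +15..+30, exactly 16
per electrode (the boundary inclusion was chosen to make the count 16).
Mean activity averages the window over FZ/CZ/PZ; peak latency is the
within-window argmax per central electrode (ties earliest), averaged
across the three; scalp profiles are window means floored at zero and
scaled by the maximum.

## Reference study scale and runtimes

The packaged study runs 6 teams x 10 games (one-quarter of the full
21 x 20 design) so the complete chain — simulation through death
placement — finishes in a few minutes on one CPU; the pipeline accepts
the full design unchanged. Per-game feature matrices are float32, and
likelihood evaluation reuses one Cholesky solve for the shared quadratic
term across classes. At this scale the synthetic study reproduces the
qualitative result pattern: fused Kill-vs-Null AUC ≈ 0.99 and at least
as high as either single source in nearly every team, own-role death
AUC above other-role for both roles, kill mismatch ≈ 13 ticks with the
cross-game reconstruction ranking essentially perfect, and EEG-informed
death placement recovering ~70% of deaths within 2 ticks where the
prior-only baseline recovers none.

## Known limitations

* The noise model is spatially and temporally white by default; no
  artifacts, drifts, or inter-electrode correlation.
* ERP templates are rigid (no amplitude variability, habituation, or
  learning effects across games).
* The kill and death decoders run separately; no joint decoding, and at
  most one death per segment is modelled.
* Between-team training assumes a shared montage and feature space
  across teams.
* Real-data ingestion (mastoid re-reference, 0.1–40 Hz bandpass,
  polyphase decimation to 60 Hz) is a thin optional stage; no native
  vendor file readers.
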