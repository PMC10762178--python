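# Methods

## Model and scope

The package addresses model-order selection for (over)determined ICA:
observed channels `X (p×n)` are assumed to be noiseless or lightly noisy
linear mixtures `X = A S` of `q ≤ p/2` mutually independent, non-Gaussian
source rows.  The estimator never sees `A` or `S`; it only asks, for each
candidate `q`, whether `q`-component decompositions are *stable under
resampling of channels*.  Underdetermined ICA (`q > p`) and time-dependent
(functional) extensions are out of scope.

## The split-half statistic

For a random half-split of channels into blocks `B₁, B₂`, ICA is fitted to
each block with the same `q`.  Components are defined up to sign and
permutation, so the comparison uses the matrix of absolute Spearman
correlations between the two component sets (rows = block 1, columns =
block 2).  Column-wise maxima `ρ_j` match every block-2 component to its
best block-1 partner; the statistic

    R_q = min_j max_i |corr(S¹_i, S²_j)|

is the reproducibility of the *least* reproducible component.  Rank
(Spearman) correlation is the default because component amplitudes are
arbitrary and relationships between estimated components need only be
monotone; Pearson is available behind the same flag for comparison.

The q-sweep starts at 2 (a 1-component "decomposition" has no matching
structure to test), so detectable estimates lie in `2 … A_max − 1`.

Selection: `D_q = R_q − R_{q−1}` for `q = 3 … A_max`; the estimate of one
repetition is `argmin_q D_q − 1`, ties broken toward the smaller `q`
(parsimony).  If no difference is negative there is no drop; the
repetition falls back to `argmax R_q` and is counted in a diagnostic flag.
The final estimate is the mode over `Rep` repetitions, ties again toward
the smaller `q`.

Defaults: `A_max = ⌊p/2⌋` (each block must host `A_max` components),
`Rep = 10` (the vote is empirically stable at this size on the simulated
designs), FastICA backend, Spearman correlation.

## ICA backends

All backends share one preprocessing path: center, then whiten onto the
`q` leading principal directions (SVD; right singular vectors scaled to
unit variance).  A backend therefore only returns a `q×q` rotation.  Two
consequences are load-bearing:

* Reconstruction `X̂ = mean + Â Ŝ` is the rank-`q` principal-subspace
  reconstruction, so the residual norm is non-increasing in `q` — the DW
  comparator depends on this.
* When `q` exceeds the numerical rank (noiseless simulations), the extra
  whitened rows are unit-variance numerical noise.  This is intentional:
  those directions are irreproducible across blocks, which is precisely
  the signal the drop detector reads.  Singular values are floored at
  `1e-12` relative only inside the (reported, otherwise unused) unmixing
  map.

Backends: FastICA via scikit-learn, extended Infomax via mne, and JADE
implemented in-package (fourth-order cumulant matrices jointly
diagonalized by Givens rotations, the classical formulation).  Extended
Infomax separates certain sub-Gaussian waveform pairs of the catalog less
sharply (best-match |corr| ≈ 0.8 for one pair, independent of the
iteration budget); its determination behaviour is nevertheless correct,
which is the property the package claims.

Non-convergence policy: a fit *fails* only when the backend raises or
returns non-finite output — then the corresponding `R_q` is recorded as
missing, and both adjacent differences are dropped rather than bridged
(conservative: never fabricate a drop).  A backend that merely exhausts
its iteration budget returns its final iterate flagged `converged=False`
and the sweep uses it; discarding such fits would systematically erase the
collapse region on rank-deficient data, where FastICA often cannot meet
its tolerance on pure-noise directions.  Retries (default 3) re-seed with
`seed + 1000·attempt`; JADE is deterministic and is not retried.

## Comparator methods

* **Durbin–Watson.**  `DW = Σ_{t≥2}(r_t − r_{t−1})² / Σ_t r_t²` per
  residual channel, bounded in `[0, 4]`, ≈ 2 for white noise.  The
  original selection is visual (a heatmap); the automated surrogate takes
  the `q` before the largest increase of the mean DW and labels itself in
  `method_flag`.  At `q = min(p, n)` the retained basis is full, the
  reconstruction is the identity by construction, and DW is reported as 0
  with a warning; for smaller `q` the projection residual is used as
  computed, even when it is numerically tiny.
* **Known-source correlation.**  Per `q`, the best absolute correlation
  between any component and the supplied `y`; smallest `q` attaining the
  global maximum (within 1e-9) wins.  Pearson by default, flag-switchable.
* **ICA-by-Blocks.**  `B` near-equal random blocks (sizes differ by ≤ 1),
  constraint `A_max ≤ ⌊p/B⌋`, per-`q` score = minimum over block pairs of
  the same min-of-column-max statistic, one split only, selected with the
  same drop rule (an automated surrogate for the original visual plot).
  With `B = 2` and Spearman correlation it reproduces a single split-half
  repetition exactly — a regression test ties the two code paths together.

## Synthetic data

The catalog holds 8 waveforms chosen to mimic the qualitative variety of
EEG constituents while staying mutually near-independent: 10-, 6- and
21-cycle/window sine, sawtooth and square waves; a 2→30 cycle linear
chirp; a sparse random spike train; a positive raised-cosine blink train;
low-pass-filtered Gaussian noise (slow drift); and i.i.d. Laplace noise.
Frequencies are in cycles per n-sample window, all multiplied by a
`freq_scale` knob that realizes "different frequency range" study
variants.  Every row is standardized to zero mean, unit variance;
deterministic waveforms ignore the seed, stochastic ones depend only on
`(seed, catalog slot)` so that requesting fewer sources never changes the
shared rows.  Measured pairwise |Pearson r| stays below 0.3 at n ≥ 500
(typically below 0.2).

Mixing matrices are i.i.d. standard normal, redrawn wholesale if the
condition number exceeds 1e8.  Noise, when requested, is added to the
*mixtures* (the conventional reading of a mixed-signal SNR): per-row
i.i.d. Gaussian, exactly scaled so that `10·log10(P_signal/P_noise)`
equals the requested dB figure for every row.

What the generator does **not** emulate: volume conduction with realistic
lead fields, 1/f spectra, non-stationarity, channel-correlated noise, or
inter-source dependence.  Passing tests on these simulations therefore
show that the estimator recovers the dimension of a well-posed linear
mixture of near-independent sources — the regime the method assumes — not
that it is calibrated for any particular recording setup.  Real recordings
enter through `read_matrix` (delimited text, one row per channel) and get
no special treatment.

## Numerical choices and degenerate inputs

* Spearman correlations use average ranks on ties (rank-then-Pearson);
  values are clipped to `[−1, 1]` against round-off.
* Constant (zero-variance) components correlate as 0 with a warning —
  treating a degenerate component as pure noise biases `R_q` downward,
  the safe direction for drop detection.
* All-zero residuals define `DW = 0` (perfect reconstruction) with a
  warning; `dw_statistic` requires `n ≥ 2`.
* `simulate_sources` requires `n ≥ 64`, `q ≥ 2`, and at most the catalog
  size; `SignalMatrix` requires finite entries, `p ≥ 2`, `n ≥ 4`, and
  warns when `n < 10·p`.
* Seeds: every stochastic step is driven by integer seeds derived
  arithmetically from the caller's seed (per repetition, per block, per
  candidate `q`), kept below 2³¹; identical inputs and seeds give
  bit-identical outputs on all paths.

## Benchmark harness

The accuracy experiment fixes one source set, redraws the mixing matrix
per run, and reports `100·m/N` percent correct per method, retaining every
per-run estimate; method failures are recorded as `"failed: <reason>"`
entries and count as incorrect, never dropped.  The robustness sweep
varies one axis — channels {12, 20, 30, 40}, lengths {256, 512, 1024,
2048}, SNR {none, 20, 10, 5} dB, or `freq_scale` {0.5, 1, 2} — holding the
rest at p=30, n=512, noiseless, `freq_scale`=1.  Default suite and
acceptance runs use N = 10–25 runs and n = 500–512 samples; results at
these sizes are already deterministic in practice (unanimous votes).

## Known limitations

* The drop rule assumes a drop exists; on data whose reproducibility
  profile rises monotonically (e.g. too-small `A_max`) the fallback flags
  itself but the estimate is weakly grounded.
* Noisy regimes at low SNR blur the collapse and can shift the vote by
  ±1; the method's own repetition vote is the only mitigation provided.
* The DW comparator inherits the weaknesses it is benchmarked for (large
  cross-channel variance, structure dependence); its automated rule is a
  formalization of a visual procedure, not a validated criterion.
* JADE builds `q(q+1)/2` cumulant matrices of size `q×q`; beyond a few
  dozen components this dominates runtime.
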