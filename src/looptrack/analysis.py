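"""Place-cell detection and Bayesian position decoding for 1D tracks.

The pipeline operates on deconvolved per-frame event-amplitude trains
aligned to a position trace:

1. *Binarization* — events are kept when their amplitude exceeds
   median + 4 MAD of the raw trace (MAD unscaled, no normal-consistency
   factor).
2. *Tuning curves* — binarized events are binned into 4 cm spatial bins,
   occupancy-normalized to events/s, and smoothed with a Gaussian filter
   (SD = 2 bins), wrapping on circular tracks.
3. *Significance* — 1000 per-lap circular shuffles of the events relative
   to position build surrogate tuning curves; bins whose true rate exceeds
   the per-bin 99th percentile of the surrogates are candidate field bins.
4. *Field criteria* — a place field is a maximal run of 3 to 24 consecutive
   significant bins (12 to <100 cm) in which events occur on at least 50%
   of laps; a cell with at least one surviving field is a place cell.
5. *Metrics* — sensitivity (fraction of laps with an in-field event),
   specificity (in-field fraction of each lap's events), spatial
   information (bits/event, Skaggs), rate-map correlation and population-
   vector shift alignment for remapping.
6. *Decoding* — a naive Bayes decoder from binned mean activity:

       P(pos | a) = C * (prod_i f_i(pos)^a_i) * exp(-tau * sum_i f_i(pos))

   evaluated in log space over windows of tau seconds, with leave-one-lap-
   out cross-validation, cell subsampling, and chance levels (L/4 on a
   circular track; cell-label shuffling otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

BIN_WIDTH_MM = 40.0        # 4 cm spatial bins
SMOOTHING_SD_BINS = 2.0    # Gaussian smoothing SD, in bins
MIN_FIELD_BINS = 3         # >= 12 cm
MAX_FIELD_BINS = 25        # field must be < 25 bins (< 100 cm)
MIN_LAP_FRACTION = 0.5     # events required on >= 50% of laps


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class EventTrain:
    """Per-frame event amplitudes for one ROI, aligned to position."""

    amplitudes: np.ndarray      # (n_frames,) >= 0
    frame_period_s: float
    position_mm: np.ndarray     # (n_frames,)
    lap: np.ndarray             # (n_frames,) int

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.lap = np.asarray(self.lap, dtype=int)
        if np.any(self.amplitudes < 0):
            raise ValueError("event amplitudes must be non-negative")
        if not (len(self.amplitudes) == len(self.position_mm) == len(self.lap)):
            raise ValueError("amplitudes, position and lap must align")


@dataclass
class OccupancyMap:
    """Dwell time per spatial bin and its normalization p_i."""

    dwell_s: np.ndarray
    bin_width_mm: float
    circular: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.dwell_s)

    @property
    def p(self) -> np.ndarray:
        total = self.dwell_s.sum()
        return self.dwell_s / total if total > 0 else self.dwell_s


@dataclass
class TuningCurve:
    """Occupancy-normalized, smoothed event rate per spatial bin."""

    rate: np.ndarray            # smoothed, events/s
    raw_rate: np.ndarray        # pre-smoothing
    counts: np.ndarray          # binarized event counts per bin
    zero_dwell: np.ndarray      # flagged bins with no occupancy

    @property
    def n_bins(self) -> int:
        return len(self.rate)

    def mean_rate(self, occ: OccupancyMap) -> float:
        return float(np.sum(occ.p * self.rate))


@dataclass
class PlaceField:
    """Maximal run of significant bins, possibly wrapping: [start, end)."""

    start_bin: int
    end_bin: int          # exclusive, modulo n_bins
    n_bins_total: int
    peak_bin: int

    @property
    def width_bins(self) -> int:
        return (self.end_bin - self.start_bin) % self.n_bins_total or self.n_bins_total

    @property
    def bins(self) -> np.ndarray:
        return (np.arange(self.start_bin, self.start_bin + self.width_bins)
                % self.n_bins_total)


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def binarize_events(amplitudes: np.ndarray, raw_trace: np.ndarray,
                    n_mads: float = 4.0) -> np.ndarray:
    """Zero out events below median(raw) + n_mads * MAD(raw).

    The MAD is unscaled (no 1.4826 factor).  A constant raw trace has MAD 0;
    all nonzero events are then retained, with a warning.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    raw = np.asarray(raw_trace, dtype=float)
    if amplitudes.shape != raw.shape:
        raise ValueError("amplitude train and raw trace must be equal length")
    med = np.median(raw)
    mad = np.median(np.abs(raw - med))
    if mad == 0:
        warnings.warn("raw trace has zero MAD; retaining all nonzero events")
        return np.where(amplitudes > 0, amplitudes, 0.0)
    threshold = med + n_mads * mad
    return np.where(amplitudes > threshold, amplitudes, 0.0)


def select_significant_transients(dff: np.ndarray, n_sds: float = 3.0) -> np.ndarray:
    """Boolean mask of samples more than n_sds SDs above the trace mean.

    Used for amplitude/frequency summaries only, not for field detection.
    """
    dff = np.asarray(dff, dtype=float)
    if not np.all(np.isfinite(dff)):
        raise ValueError("trace must be finite")
    sd = dff.std()
    if sd == 0:
        return np.zeros(dff.shape, dtype=bool)
    return dff > dff.mean() + n_sds * sd


# ---------------------------------------------------------------------------
# Occupancy and tuning
# ---------------------------------------------------------------------------

def position_to_bin(position_mm: np.ndarray, track_length_mm: float,
                    n_bins: int) -> np.ndarray:
    idx = np.floor(np.asarray(position_mm) / track_length_mm * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def default_n_bins(track_length_mm: float,
                   bin_width_mm: float = BIN_WIDTH_MM) -> int:
    return int(round(track_length_mm / bin_width_mm))


def compute_occupancy(position_mm: np.ndarray, frame_period_s: float,
                      track_length_mm: float, n_bins: int | None = None,
                      circular: bool = True,
                      bin_width_mm: float = BIN_WIDTH_MM) -> OccupancyMap:
    """Dwell time per spatial bin from a frame-sampled position trace."""
    if n_bins is None:
        n_bins = default_n_bins(track_length_mm, bin_width_mm)
    idx = position_to_bin(position_mm, track_length_mm, n_bins)
    dwell = np.bincount(idx, minlength=n_bins).astype(float) * frame_period_s
    return OccupancyMap(dwell_s=dwell, bin_width_mm=track_length_mm / n_bins,
                        circular=circular)


def _smooth(rate: np.ndarray, sd_bins: float, circular: bool) -> np.ndarray:
    if sd_bins <= 0:
        return rate.copy()
    mode = "wrap" if circular else "nearest"
    return gaussian_filter1d(rate, sd_bins, mode=mode, truncate=4.0)


def compute_tuning(ev: EventTrain, occ: OccupancyMap,
                   smoothing_sd_bins: float = SMOOTHING_SD_BINS,
                   track_length_mm: float | None = None) -> TuningCurve:
    """Occupancy-normalized event rate per bin, Gaussian smoothed.

    Bins with zero dwell get rate 0 and are flagged.  Pre-smoothing, the
    curve conserves the event count: sum(rate * dwell) equals the number of
    binarized events.
    """
    if occ.dwell_s.sum() <= 0:
        raise ValueError("occupancy is zero everywhere")
    B = occ.n_bins
    L = track_length_mm if track_length_mm is not None else occ.bin_width_mm * B
    idx = position_to_bin(ev.position_mm, L, B)
    event_frames = ev.amplitudes > 0
    counts = np.bincount(idx[event_frames], minlength=B).astype(float)
    zero_dwell = occ.dwell_s == 0
    raw_rate = np.zeros(B)
    np.divide(counts, occ.dwell_s, out=raw_rate, where=~zero_dwell)
    rate = _smooth(raw_rate, smoothing_sd_bins, occ.circular)
    return TuningCurve(rate=rate, raw_rate=raw_rate, counts=counts,
                       zero_dwell=zero_dwell)


# ---------------------------------------------------------------------------
# Circular-shuffle significance
# ---------------------------------------------------------------------------

def shuffle_threshold(ev: EventTrain, occ: OccupancyMap,
                      n_shuffles: int = 1000, percentile: float = 99.0,
                      seed: int | None = None,
                      smoothing_sd_bins: float = SMOOTHING_SD_BINS,
                      track_length_mm: float | None = None,
                      rng: np.random.Generator | None = None,
                      return_surrogates: bool = False):
    """Per-bin significance threshold from per-lap circular shuffles.

    Each surrogate circularly shifts the events relative to the position
    trace within every lap by an independent uniform frame offset, then
    recomputes the (smoothed, occupancy-normalized) tuning curve.  The
    threshold is the per-bin ``percentile`` of the surrogate curves.
    Shifting events rather than occupancy is the same operation (the dwell
    map is invariant under a relative circular shift).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    B = occ.n_bins
    L = track_length_mm if track_length_mm is not None else occ.bin_width_mm * B
    laps = np.unique(ev.lap)
    if len(laps) < 2:
        raise ValueError("need at least 2 laps for the shuffle test")
    idx = position_to_bin(ev.position_mm, L, B)
    counts = np.zeros((n_shuffles, B))
    for lap in laps:
        in_lap = np.flatnonzero(ev.lap == lap)
        n_lap = len(in_lap)
        bins_local = idx[in_lap]
        ev_local = np.flatnonzero(ev.amplitudes[in_lap] > 0)
        if len(ev_local) == 0:
            continue
        offsets = rng.integers(0, n_lap, size=n_shuffles)
        # shifted event positions: frame (e + o) mod n_lap, all shuffles at once
        shifted = (ev_local[None, :] + offsets[:, None]) % n_lap
        target_bins = bins_local[shifted]
        rows = np.repeat(np.arange(n_shuffles), len(ev_local))
        np.add.at(counts, (rows, target_bins.ravel()), 1.0)
    zero_dwell = occ.dwell_s == 0
    rates = np.zeros_like(counts)
    np.divide(counts, occ.dwell_s[None, :], out=rates,
              where=~zero_dwell[None, :])
    if smoothing_sd_bins > 0:
        mode = "wrap" if occ.circular else "nearest"
        rates = gaussian_filter1d(rates, smoothing_sd_bins, axis=1, mode=mode,
                                  truncate=4.0)
    threshold = np.percentile(rates, percentile, axis=0)
    if return_surrogates:
        return threshold, rates
    return threshold


def per_lap_event_bins(ev: EventTrain, n_bins: int,
                       track_length_mm: float) -> list[np.ndarray]:
    """Spatial bin index of every binarized event, grouped per lap."""
    idx = position_to_bin(ev.position_mm, track_length_mm, n_bins)
    out = []
    for lap in np.unique(ev.lap):
        sel = (ev.lap == lap) & (ev.amplitudes > 0)
        out.append(idx[sel])
    return out


def _circular_runs(sig: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array: (start, length)."""
    B = len(sig)
    if sig.all():
        return [(0, B)]
    if not sig.any():
        return []
    ext = np.concatenate([sig, sig])
    runs = []
    i = 0
    while i < B:
        if ext[i] and not ext[i - 1 if i > 0 else B - 1]:
            j = i
            while ext[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def detect_place_fields(curve: TuningCurve, threshold: np.ndarray,
                        lap_event_bins: list[np.ndarray],
                        circular: bool = True,
                        min_bins: int = MIN_FIELD_BINS,
                        max_bins: int = MAX_FIELD_BINS,
                        min_lap_fraction: float = MIN_LAP_FRACTION,
                        ) -> list[PlaceField]:
    """Candidate fields = maximal supra-threshold runs (wrapping on circular
    tracks), kept when 3 <= width < 25 bins and events occur within the run
    on at least half of the laps.  A cell is a place cell iff any field
    survives."""
    B = curve.n_bins
    sig = curve.rate > threshold
    runs = _circular_runs(sig) if circular else _linear_runs(sig)
    fields = []
    n_laps = len(lap_event_bins)
    for start, width in runs:
        if not (min_bins <= width < max_bins):
            continue
        run_bins = set(((start + np.arange(width)) % B).tolist())
        laps_with = sum(1 for bins in lap_event_bins
                        if any(int(b) in run_bins for b in bins))
        if n_laps == 0 or laps_with / n_laps < min_lap_fraction:
            continue
        idx = (start + np.arange(width)) % B
        peak = int(idx[np.argmax(curve.rate[idx])])
        fields.append(PlaceField(start_bin=start, end_bin=(start + width) % B,
                                 n_bins_total=B, peak_bin=peak))
    return fields


def _linear_runs(sig: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    i, B = 0, len(sig)
    while i < B:
        if sig[i]:
            j = i
            while j < B and sig[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def is_place_cell(curve: TuningCurve, threshold: np.ndarray,
                  lap_event_bins: list[np.ndarray], **kwargs) -> bool:
    return len(detect_place_fields(curve, threshold, lap_event_bins,
                                   **kwargs)) > 0


# ---------------------------------------------------------------------------
# Per-cell metrics
# ---------------------------------------------------------------------------

def sensitivity(fields: list[PlaceField],
                lap_event_bins: list[np.ndarray]) -> float:
    """Fraction of laps with at least one in-field event, field-averaged."""
    if not fields:
        raise ValueError("sensitivity requires at least one field")
    n_laps = len(lap_event_bins)
    vals = []
    for f in fields:
        fb = set(f.bins.tolist())
        hit = sum(1 for bins in lap_event_bins
                  if any(int(b) in fb for b in bins))
        vals.append(hit / n_laps)
    return float(np.mean(vals))


def specificity(fields: list[PlaceField],
                lap_event_bins: list[np.ndarray]) -> float:
    """Per-lap in-field event fraction, averaged over laps with events,
    then over fields.  NaN when no lap has any event."""
    if not fields:
        raise ValueError("specificity requires at least one field")
    vals = []
    for f in fields:
        fb = set(f.bins.tolist())
        ratios = []
        for bins in lap_event_bins:
            if len(bins) == 0:
                continue  # zero-event laps excluded from the average
            in_field = sum(1 for b in bins if int(b) in fb)
            ratios.append(in_field / len(bins))
        vals.append(np.mean(ratios) if ratios else np.nan)
    return float(np.nanmean(vals)) if not all(np.isnan(v) for v in vals) else float("nan")


def spatial_information(curve: TuningCurve, occ: OccupancyMap) -> float:
    """Skaggs spatial information, bits/event:
    SI = sum_i p_i (lam_i / lam_bar) log2(lam_i / lam_bar)."""
    lam = curve.rate
    p = occ.p
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return float("nan")
    ratio = lam / lam_bar
    terms = np.where(lam > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)),
                     0.0)
    return float(terms.sum())


def rate_map_correlation(curve_a: np.ndarray | TuningCurve,
                         curve_b: np.ndarray | TuningCurve) -> float:
    """Pearson correlation between two per-bin rate maps (NaN when either
    map has zero variance)."""
    a = curve_a.rate if isinstance(curve_a, TuningCurve) else np.asarray(curve_a)
    b = curve_b.rate if isinstance(curve_b, TuningCurve) else np.asarray(curve_b)
    if a.shape != b.shape:
        raise ValueError("rate maps must have equal length")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def optimal_circular_shift(pop_a: np.ndarray, pop_b: np.ndarray
                           ) -> tuple[int, float]:
    """Shift s* (in bins) of map A that best matches map B.

    For each candidate shift the N-cell population vectors are correlated
    bin by bin between rolled A and B and averaged; s* maximizes the mean
    (ties -> smallest shift).  If B was produced by rotating A right by k
    bins, s* = k; rolling B left by s* aligns it back to A.
    """
    pop_a = np.asarray(pop_a, float)
    pop_b = np.asarray(pop_b, float)
    if pop_a.shape != pop_b.shape:
        raise ValueError("population maps must have equal shape")
    B = pop_a.shape[1]
    best_s, best_val = 0, -np.inf
    for s in range(B):
        rolled = np.roll(pop_a, s, axis=1)
        vals = []
        for b in range(B):
            x, y = rolled[:, b], pop_b[:, b]
            if x.std() == 0 or y.std() == 0:
                continue
            vals.append(np.corrcoef(x, y)[0, 1])
        mean_val = np.mean(vals) if vals else -np.inf
        if mean_val > best_val + 1e-12:
            best_val, best_s = mean_val, s
    return best_s, float(best_val)


# ---------------------------------------------------------------------------
# Naive Bayes position decoder (sklearn-style estimator)
# ---------------------------------------------------------------------------

class BayesDecoder:
    """Naive Bayes population position decoder.

    Fits per-cell mean binned activity f_i(pos) (events/s) from training
    frames and inverts it over decoding windows of ``tau_s`` seconds:

        log P(pos | a) = sum_i a_i ln f_i(pos) - tau * sum_i f_i(pos) + ln C

    where a_i is cell i's event count in the window.  Zero rates are floored
    at ``rate_floor`` so the log-likelihood stays finite.  Decoded position
    is the argmax bin (lowest index on ties).

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` with X the
    (n_frames, n_cells) binarized activity and y the per-frame position bin,
    then ``predict`` / ``predict_proba`` on (n_windows, n_cells) counts.
    """

    def __init__(self, n_bins: int = 50, tau_s: float = 0.5,
                 frame_period_s: float = 1.0 / 30.0, rate_floor: float = 1e-4):
        self.n_bins = n_bins
        self.tau_s = tau_s
        self.frame_period_s = frame_period_s
        self.rate_floor = rate_floor

    # -- sklearn protocol ------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_bins": self.n_bins, "tau_s": self.tau_s,
                "frame_period_s": self.frame_period_s,
                "rate_floor": self.rate_floor}

    def set_params(self, **params) -> "BayesDecoder":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BayesDecoder":
        """Estimate f_i(pos) = mean activity of cell i in bin pos (events/s)."""
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_frames, n_cells) aligned with y")
        B = self.n_bins
        active = (X > 0).astype(float)
        occupancy = np.bincount(y, minlength=B).astype(float)
        sums = np.zeros((B, X.shape[1]))
        np.add.at(sums, y, active)
        with np.errstate(invalid="ignore"):
            mean_per_frame = sums / occupancy[:, None]
        self.empty_bins_ = occupancy == 0
        mean_per_frame[self.empty_bins_] = 0.0
        rates = mean_per_frame.T / self.frame_period_s   # (n_cells, B), events/s
        self.rates_ = np.maximum(rates, self.rate_floor)
        self.n_cells_ = X.shape[1]
        with np.errstate(divide="ignore"):  # -inf only when rate_floor == 0
            self.log_rates_ = np.log(self.rates_)
        return self

    def predict_log_proba(self, A: np.ndarray) -> np.ndarray:
        """Normalized log posterior over bins for window count matrix A."""
        A = np.atleast_2d(np.asarray(A, float))
        if A.shape[1] != self.n_cells_:
            raise ValueError("cell count mismatch")
        log_post = A @ self.log_rates_ - self.tau_s * self.rates_.sum(axis=0)
        log_post -= log_post.max(axis=1, keepdims=True)
        log_post -= np.log(np.exp(log_post).sum(axis=1, keepdims=True))
        return log_post

    def predict_proba(self, A: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(A))

    def predict(self, A: np.ndarray) -> np.ndarray:
        """Decoded bin per window: argmax posterior, lowest index on ties."""
        return np.argmax(self.predict_log_proba(A), axis=1)


def fit_decoder(activity: np.ndarray, pos_bins: np.ndarray, n_bins: int,
                frame_period_s: float = 1.0 / 30.0, tau_s: float = 0.5,
                rate_floor: float = 1e-4) -> BayesDecoder:
    """Fit a BayesDecoder on training frames (thin functional wrapper)."""
    return BayesDecoder(n_bins=n_bins, tau_s=tau_s,
                        frame_period_s=frame_period_s,
                        rate_floor=rate_floor).fit(activity, pos_bins)


def decode_posterior(a: np.ndarray, model: BayesDecoder) -> np.ndarray:
    """Posterior probability over position bins for one activity vector."""
    return model.predict_proba(np.atleast_2d(a))[0]


def _window_counts(activity: np.ndarray, pos_bins: np.ndarray,
                   window_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate frames into non-overlapping decoding windows.

    Returns event counts per window per cell and the true bin at each
    window's center frame."""
    n = (len(activity) // window_frames) * window_frames
    if n == 0:
        return np.zeros((0, activity.shape[1])), np.zeros(0, dtype=int)
    act = (activity[:n] > 0).astype(float)
    A = act.reshape(-1, window_frames, activity.shape[1]).sum(axis=1)
    centers = pos_bins[np.arange(window_frames // 2, n, window_frames)]
    return A, centers


def bin_distance(a: np.ndarray, b: np.ndarray, n_bins: int,
                 circular: bool = True) -> np.ndarray:
    d = np.abs(np.asarray(a) - np.asarray(b))
    if circular:
        d = np.minimum(d, n_bins - d)
    return d


def decoding_error(decoded_bins: np.ndarray, true_bins: np.ndarray,
                   n_bins: int, bin_width_cm: float = 4.0,
                   circular: bool = True) -> float:
    """Mean absolute decoding error in cm (circular distance when the
    track is circular)."""
    if len(decoded_bins) != len(true_bins):
        raise ValueError("decoded and true sequences must align")
    d = bin_distance(decoded_bins, true_bins, n_bins, circular)
    return float(np.mean(d) * bin_width_cm)


def chance_level_circular(track_length_cm: float) -> float:
    """Expected absolute circular distance between independent uniform
    points on a ring: track length / 4."""
    if track_length_cm <= 0:
        raise ValueError("track length must be positive")
    return track_length_cm / 4.0


def chance_by_label_shuffle(model: BayesDecoder, A_test: np.ndarray,
                            true_bins: np.ndarray, n_shuffles: int = 100,
                            seed: int | None = None, bin_width_cm: float = 4.0,
                            circular: bool = True) -> dict:
    """Chance decoding-error distribution from cell-label permutation.

    Each shuffle permutes the cell identities of the test activity (the
    identity permutation is allowed), decodes, and records the mean error.
    The observed error's rank gives the empirical p value
    p = (1 + #{shuffle error <= observed}) / (n_shuffles + 1).
    """
    if model.n_cells_ < 2:
        raise ValueError("label shuffling needs at least 2 cells")
    rng = np.random.default_rng(seed)
    observed = decoding_error(model.predict(A_test), true_bins, model.n_bins,
                              bin_width_cm, circular)
    errs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(model.n_cells_)
        errs[s] = decoding_error(model.predict(A_test[:, perm]), true_bins,
                                 model.n_bins, bin_width_cm, circular)
    p = (1 + np.sum(errs <= observed)) / (n_shuffles + 1)
    return {"observed_error_cm": observed, "shuffle_errors_cm": errs,
            "p_value": float(p)}


def crossval_decode(activity: np.ndarray, pos_bins: np.ndarray,
                    laps: np.ndarray, n_bins: int,
                    frame_period_s: float = 1.0 / 30.0, tau_s: float = 0.5,
                    subsample: int = 500, repeats: int = 50,
                    seed: int | None = None, bin_width_cm: float = 4.0,
                    circular: bool = True, rate_floor: float = 1e-4) -> dict:
    """Leave-one-lap-out cross-validated decoding error with cell
    subsampling.

    For every held-out lap a decoder is fit on the remaining laps (all
    cells; subsampling selects decoder rows, so per-repeat refits are
    unnecessary).  Each repeat draws ``subsample`` cells without replacement
    (all cells when fewer are available) and aggregates the mean absolute
    error in cm over all held-out windows.  Returns mean +/- SD over repeats.
    """
    activity = np.asarray(activity, float)
    laps = np.asarray(laps, int)
    lap_ids = np.unique(laps)
    if len(lap_ids) < 2:
        raise ValueError("cross-validation needs at least 2 laps")
    n_cells = activity.shape[1]
    window_frames = max(1, int(round(tau_s / frame_period_s)))
    rng = np.random.default_rng(seed)

    # one full-population fit per held-out lap, reused across repeats
    folds = []
    for lap in lap_ids:
        train = laps != lap
        model = BayesDecoder(n_bins=n_bins, tau_s=tau_s,
                             frame_period_s=frame_period_s,
                             rate_floor=rate_floor).fit(
            activity[train], pos_bins[train])
        A, truth = _window_counts(activity[~train], pos_bins[~train],
                                  window_frames)
        folds.append((model, A, truth))

    per_repeat = np.empty(repeats)
    k = min(subsample, n_cells)
    for r in range(repeats):
        cells = rng.choice(n_cells, size=k, replace=False)
        dists, weights = [], []
        for model, A, truth in folds:
            if len(truth) == 0:
                continue
            sub = BayesDecoder(n_bins=n_bins, tau_s=tau_s,
                               frame_period_s=frame_period_s,
                               rate_floor=rate_floor)
            sub.rates_ = model.rates_[cells]
            sub.log_rates_ = model.log_rates_[cells]
            sub.n_cells_ = k
            sub.empty_bins_ = model.empty_bins_
            err = decoding_error(sub.predict(A[:, cells]), truth, n_bins,
                                 bin_width_cm, circular)
            dists.append(err)
            weights.append(len(truth))
        per_repeat[r] = np.average(dists, weights=weights)
    return {"mean_error_cm": float(per_repeat.mean()),
            "sd_error_cm": float(per_repeat.std(ddof=1)) if repeats > 1 else 0.0,
            "per_repeat_cm": per_repeat,
            "n_cells_used": k,
            "window_frames": window_frames}


# ---------------------------------------------------------------------------
# Proportion test
# ---------------------------------------------------------------------------

def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int
                         ) -> tuple[float, float]:
    """Pooled two-sample proportion z test.

    z = (p2 - p1) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n2)), two-sided
    normal p.  Degenerate pooled proportions (0 or 1) return NaN with a
    warning.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n and n > 0):
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    if pool in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z undefined")
        return float("nan"), float("nan")
    z = (p2 - p1) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
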