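"""Position-weight-matrix scanning, motif occurrence, EM discovery, comparison.

A PWM stores per-position base probabilities over (A, C, G, T) plus a
background distribution; windows are scored as the sum of per-position
log2 odds, on both strands. Per-peak occurrence uses a threshold expressed
as a fraction of the motif's maximum achievable score, and multiple versions
of a factor's motif are combined as a non-duplicate union per peak.

De novo discovery fits a zero-or-one-occurrence-per-sequence (ZOOPS)
mixture by expectation-maximisation over both strands, restarted from
several seeded initialisations and keeping the best by log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G
N_CODE = 4

DEFAULT_THRESHOLD_FRACTION = 0.8
DEFAULT_EM_RESTARTS = 10
DEFAULT_EM_MAX_ITER = 200
EM_PSEUDOCOUNT = 0.25


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T/N string to int8 codes (N and unknowns -> 4)."""
    table = np.full(256, N_CODE, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


def reverse_complement(sequence: str) -> str:
    codes = encode(sequence)
    if (codes == N_CODE).any():
        comp = np.append(_COMPLEMENT, np.int8(N_CODE))
        return decode(comp[codes[::-1]])
    return decode(_COMPLEMENT[codes[::-1]])


@dataclass
class PWM:
    """Base-probability matrix of a binding motif.

    ``matrix`` is width x 4 over (A, C, G, T); every row sums to 1 (within
    1e-9 after pseudocount regularisation). ``background`` is the null base
    distribution used in log-odds scoring.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.matrix <= 0).any() or (self.background <= 0).any():
            raise ValueError("probabilities must be strictly positive (apply a pseudocount)")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """width x 4 log2(p / background)."""
        return np.log2(self.matrix / self.background[None, :])

    @property
    def max_score(self) -> float:
        """Largest achievable log-odds score (the consensus score)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id + "_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            source=self.source,
        )

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, pseudocount: float = 0.5,
                    background: np.ndarray | None = None, source: str = "counts") -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else background
        return cls(motif_id, matrix, bg, source)

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p_consensus: float = 0.85,
                       source: str = "consensus") -> "PWM":
        w = len(consensus)
        matrix = np.full((w, 4), (1.0 - p_consensus) / 3.0)
        for i, base in enumerate(consensus.upper()):
            matrix[i, _BASE_INDEX[base]] = p_consensus
        return cls(motif_id, matrix, source=source)


# Illustrative default motifs for the two factors, derived from the published
# consensus sites (TCF/LEF: CTTTG(T/A)(T/A); RUNX/AML core: TGTGGT). These are
# synthetic consensus-based approximations built in-package, not database
# matrices; simulation and demo defaults only.
DEFAULT_PWMS: dict[str, PWM] = {
    "TCF7_v1": PWM.from_consensus("TCF7_v1", "CCTTTGATCTTT", source="synthetic-consensus"),
    "TCF7_v2": PWM.from_consensus("TCF7_v2", "ACTTTGTTAG", source="synthetic-consensus"),
    "RUNX1_v1": PWM.from_consensus("RUNX1_v1", "TGTGGTTT", source="synthetic-consensus"),
    "RUNX1_v2": PWM.from_consensus("RUNX1_v2", "AACCACAG", source="synthetic-consensus"),
}


@dataclass(frozen=True)
class MotifHit:
    position: int   # window start on the forward strand
    strand: str     # '+' or '-'
    score: float    # log2 odds


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window on the given strand matrix; invalid (N) windows -> -inf.

    Returns (scores, valid_mask) for windows starting at 0..L-w.
    """
    w = log_odds.shape[0]
    L = len(codes)
    if L < w:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows == N_CODE).any(axis=1)
    safe = np.where(windows == N_CODE, 0, windows)
    scores = log_odds[np.arange(w)[None, :], safe].sum(axis=1)
    scores = np.where(valid, scores, -np.inf)
    return scores, valid


def scan_pwm(sequence: str, pwm: PWM, score_threshold: float) -> list[MotifHit]:
    """All windows on both strands scoring >= threshold (log2 odds).

    Positions are window starts on the forward strand; windows containing N
    are skipped. Sequences shorter than the motif yield an empty list.
    """
    codes = encode(sequence)
    if len(codes) < pwm.width:
        return []
    hits: list[MotifHit] = []
    fwd, _ = _window_scores(codes, pwm.log_odds)
    rev, _ = _window_scores(codes, pwm.reverse_complement().log_odds)
    for pos in np.nonzero(fwd >= score_threshold)[0]:
        hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
    for pos in np.nonzero(rev >= score_threshold)[0]:
        hits.append(MotifHit(int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def best_hit_score(sequence: str, pwm: PWM) -> float:
    """Best log-odds score over all windows and strands (-inf if none valid)."""
    codes = encode(sequence)
    if len(codes) < pwm.width:
        return float("-inf")
    fwd, _ = _window_scores(codes, pwm.log_odds)
    rev, _ = _window_scores(codes, pwm.reverse_complement().log_odds)
    return float(max(fwd.max(initial=-np.inf), rev.max(initial=-np.inf)))


def relative_threshold(pwm: PWM, fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    """Score threshold as a fraction of the motif's maximum achievable score."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return fraction * pwm.max_score


@dataclass
class MotifOccurrence:
    """Per-peak hit table and per-factor union occurrence fractions.

    ``hits`` is indexed by peak id with one boolean column per motif version
    plus one ``<factor>_union`` column per factor (the OR over that factor's
    versions). ``fractions`` maps factor -> fraction of peaks with >= 1
    union hit; empty input yields an explicit empty report.
    """

    hits: pd.DataFrame
    fractions: dict[str, float]
    threshold_fraction: float
    empty: bool = False


def peak_motif_occurrence(
    peak_sequences: Mapping[str, str],
    pwms_by_factor: Mapping[str, Sequence[PWM]],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> MotifOccurrence:
    """Fraction of peaks containing >= 1 motif version of each factor.

    A peak counts once per factor no matter how many versions or windows
    match (non-duplicate union across versions).
    """
    names = list(peak_sequences.keys())
    if not names:
        return MotifOccurrence(hits=pd.DataFrame(), fractions={}, threshold_fraction=threshold_fraction, empty=True)
    for name, seq in peak_sequences.items():
        if seq is None or len(seq) == 0:
            raise ValueError(f"missing sequence for peak {name!r}")
    columns: dict[str, np.ndarray] = {}
    fractions: dict[str, float] = {}
    for factor, pwms in pwms_by_factor.items():
        union = np.zeros(len(names), dtype=bool)
        for pwm in pwms:
            thr = relative_threshold(pwm, threshold_fraction)
            col = np.array([best_hit_score(peak_sequences[n], pwm) >= thr for n in names])
            columns[pwm.motif_id] = col
            union |= col
        columns[f"{factor}_union"] = union
        fractions[factor] = float(union.mean())
    hits = pd.DataFrame(columns, index=pd.Index(names, name="peak_id"))
    return MotifOccurrence(hits=hits, fractions=fractions, threshold_fraction=threshold_fraction)


def sample_bound_sequences(
    peaks: pd.DataFrame,
    sequences: Mapping[str, str],
    n: int,
    seed: int,
) -> dict[str, str]:
    """Seeded sample (without replacement) of ``n`` peak sequences.

    Returned in original peak order for stability. ``sequences`` maps peak
    name to the sequence over the full peak interval.
    """
    names = peaks["name"].tolist()
    if n > len(names):
        raise ValueError(f"cannot sample {n} from {len(names)} peaks")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(names), size=n, replace=False).tolist())
    return {names[i]: sequences[names[i]] for i in range(len(names)) if i in chosen}


@dataclass
class MotifDiscoveryResult:
    pwm: PWM
    site_posteriors: pd.DataFrame   # per sequence: prob_site, best position/strand
    log_likelihood: float
    ll_trace: np.ndarray
    converged: bool
    n_iterations: int


def _stack_windows(seqs: list[np.ndarray], width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack all (forward + reverse-complement) windows of every sequence.

    Returns (windows, seq_offsets, n_windows_per_seq); windows of sequence s
    occupy rows offsets[s]:offsets[s+1], forward windows first then the
    reverse-complement of each window in the same positional order.
    """
    blocks = []
    n_win = []
    for codes in seqs:
        wv = np.lib.stride_tricks.sliding_window_view(codes, width)
        rc = _COMPLEMENT[wv[:, ::-1]]
        blocks.append(np.concatenate([wv, rc], axis=0))
        n_win.append(2 * len(wv))
    offsets = np.concatenate([[0], np.cumsum(n_win)])
    return np.concatenate(blocks, axis=0), offsets, np.asarray(n_win)


def discover_motif(
    sequences: Sequence[str],
    width: int,
    n_restarts: int = DEFAULT_EM_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    tol: float = 1e-6,
    min_sequences: int = 50,
) -> MotifDiscoveryResult:
    """ZOOPS EM motif discovery over both strands.

    Each sequence contains at most one motif occurrence (probability
    ``gamma``, position and strand uniform); the rest of the sequence is
    i.i.d. uniform background. EM alternates site posteriors (E) and
    expected-count updates of the base-probability matrix with a 0.25
    pseudocount per cell (M). The best of ``n_restarts`` seeded restarts by
    final log-likelihood is returned; if the last run never reached the
    relative tolerance, the best iterate is returned with ``converged``
    False and a warning.
    """
    if len(sequences) < min_sequences:
        raise ValueError(f"need >= {min_sequences} sequences, got {len(sequences)}")
    seqs = [encode(s) for s in sequences]
    for i, codes in enumerate(seqs):
        if len(codes) < width:
            raise ValueError(f"sequence {i} shorter than motif width {width}")
        if (codes == N_CODE).any():
            raise ValueError(f"sequence {i} contains N; EM requires unambiguous bases")

    windows, offsets, n_win = _stack_windows(seqs, width)
    n_seqs = len(seqs)
    total = windows.shape[0]
    col_idx = [windows[:, i] for i in range(width)]
    # per-sequence divisor: uniform prior over (position, strand) pairs
    per_seq_m = np.repeat(n_win.astype(float), n_win)
    seg_ids = np.repeat(np.arange(n_seqs), n_win)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, float, np.ndarray, bool, int] | None = None

    for _ in range(max(1, n_restarts)):
        # init from a random window, smoothed toward uniform
        w0 = windows[rng.integers(total)]
        theta = np.full((width, 4), 0.15)
        theta[np.arange(width), w0] = 0.55
        gamma = 0.5
        ll_trace = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            log_ratio = np.log(theta / 0.25)
            s = np.zeros(total)
            for i in range(width):
                s += log_ratio[i, col_idx[i]]
            r = np.exp(s)
            seq_sum_r = np.add.reduceat(r, offsets[:-1])
            denom = (1.0 - gamma) + gamma * seq_sum_r / n_win
            ll = float(np.sum(np.log(denom)))  # + constant background term
            ll_trace.append(ll)
            # E-step posteriors
            z = (gamma / per_seq_m) * r / denom[seg_ids]
            z0 = (1.0 - gamma) / denom
            # M-step
            counts = np.empty((width, 4))
            for i in range(width):
                counts[i] = np.bincount(col_idx[i], weights=z, minlength=4)
            counts += EM_PSEUDOCOUNT
            theta = counts / counts.sum(axis=1, keepdims=True)
            gamma = float(np.clip(1.0 - z0.mean(), 1e-6, 1 - 1e-6))
            if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) <= tol * (abs(ll_trace[-2]) + 1e-12):
                converged = True
                break
        final_ll = ll_trace[-1]
        if best is None or final_ll > best[0]:
            best = (final_ll, theta.copy(), gamma, np.asarray(ll_trace), converged, n_iter)

    assert best is not None
    final_ll, theta, gamma, ll_trace, converged, n_iter = best
    if not converged:
        warnings.warn("EM did not reach tolerance; returning best iterate", stacklevel=2)

    # final posteriors for reporting
    log_ratio = np.log(theta / 0.25)
    s = np.zeros(total)
    for i in range(width):
        s += log_ratio[i, col_idx[i]]
    r = np.exp(s)
    seq_sum_r = np.add.reduceat(r, offsets[:-1])
    denom = (1.0 - gamma) + gamma * seq_sum_r / n_win
    z = (gamma / per_seq_m) * r / denom[seg_ids]
    rows = []
    for si in range(n_seqs):
        zs = z[offsets[si]:offsets[si + 1]]
        half = n_win[si] // 2
        j = int(np.argmax(zs))
        strand = "+" if j < half else "-"
        # rc windows are stored in forward positional order, so the forward
        # start coordinate is the window index on either strand
        pos = j if j < half else j - half
        rows.append((si, float(zs.sum()), int(pos), strand, float(zs[j])))
    posteriors = pd.DataFrame(rows, columns=["sequence", "prob_site", "best_position", "best_strand", "best_posterior"])

    pwm = PWM(motif_id=f"denovo_w{width}", matrix=theta, source="de-novo")
    return MotifDiscoveryResult(
        pwm=pwm,
        site_posteriors=posteriors,
        log_likelihood=final_ll,
        ll_trace=ll_trace,
        converged=converged,
        n_iterations=n_iter,
    )


@dataclass(frozen=True)
class MotifAlignment:
    offset: int              # shift of b relative to a (column index of a where b starts)
    orientation: str         # 'same' or 'complementary'
    n_aligned: int
    similarity: float        # mean Pearson correlation of aligned probability columns
    consensus_matches: int   # aligned columns with identical consensus letters


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na < 1e-12 and nb < 1e-12:
        return 1.0
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(np.dot(da, db) / (na * nb))


def compare_motifs(pwm_a: PWM, pwm_b: PWM, min_overlap: int = 4) -> MotifAlignment:
    """Best ungapped alignment of two PWMs over both orientations.

    Slides ``pwm_b`` (and its reverse complement) across ``pwm_a`` over all
    offsets with at least ``min_overlap`` aligned columns; similarity is the
    mean Pearson correlation of the aligned probability columns. Ties prefer
    more aligned columns, then the smaller absolute offset.
    """
    best: MotifAlignment | None = None
    for orientation, mb in (("same", pwm_b.matrix), ("complementary", pwm_b.reverse_complement().matrix)):
        wa, wb = pwm_a.width, mb.shape[0]
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            a_lo, a_hi = max(0, offset), min(wa, offset + wb)
            n_aligned = a_hi - a_lo
            if n_aligned < min_overlap:
                continue
            cols_a = pwm_a.matrix[a_lo:a_hi]
            cols_b = mb[a_lo - offset:a_hi - offset]
            sims = [_column_corr(ca, cb) for ca, cb in zip(cols_a, cols_b)]
            matches = int(sum(ca.argmax() == cb.argmax() for ca, cb in zip(cols_a, cols_b)))
            cand = MotifAlignment(offset, orientation, n_aligned, float(np.mean(sims)), matches)
            if (best is None
                    or cand.similarity > best.similarity + 1e-12
                    or (abs(cand.similarity - best.similarity) <= 1e-12
                        and (cand.n_aligned, -abs(cand.offset)) > (best.n_aligned, -abs(best.offset)))):
                best = cand
    assert best is not None
    return best
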