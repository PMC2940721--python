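"""Position weight matrices, LLR scoring and binding-site annotation.

A PWM stores per-position base probabilities for a transcription factor's
binding specificity.  Candidate sites on a CRM sequence are scored by the
log-likelihood ratio (LLR) against a background nucleotide distribution,
assuming per-position additivity of binding energy.  Sites are annotated
wherever the LLR exceeds a fixed fraction (default 0.4) of the LLR of the
optimal word S_max, on either strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_BACKGROUND = np.full(4, 0.25)
DEFAULT_THRESHOLD_FRAC = 0.4
_PROB_FLOOR = 1e-6


class PwmParseError(ValueError):
    """Raised for malformed PWM blocks (names the motif and line)."""


def _encode(seq: str) -> np.ndarray:
    """DNA string -> int codes (A,C,G,T -> 0..3; anything else -> -1)."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(b)] = i
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background, in A,C,G,T column order."""

    name: str
    probs: np.ndarray                     # (width, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())
    pseudocount: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"PWM {self.name}: probs must be width x 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        if np.any(probs <= 0):
            raise ValueError(f"PWM {self.name}: probabilities must be positive")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def llr_matrix(self) -> np.ndarray:
        """Per-position, per-base ln(p/background), shape (width, 4)."""
        return np.log(self.probs / self.background)

    @property
    def llr_max(self) -> float:
        """LLR of the optimal word S_max."""
        return float(self.llr_matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """The maximal-LLR word S_max (ties broken toward A<C<G<T)."""
        return "".join(BASES[i] for i in self.llr_matrix.argmax(axis=1))

    def rc_llr_matrix(self) -> np.ndarray:
        """LLR matrix scoring the minus strand in plus-strand coordinates.

        Scoring a window w on the minus strand means scoring revcomp(w)
        against this PWM; equivalently score w with rows reversed and
        columns complemented (background is applied to the revcomp letters).
        """
        return self.llr_matrix[::-1, _COMPLEMENT_IDX]


@dataclass(frozen=True)
class BindingSite:
    """An annotated binding site on the plus-strand coordinate system.

    Half-open interval [start, start+length); a minus-strand site's
    coordinates still refer to the plus strand.
    """

    tf: str
    start: int
    length: int
    strand: str       # '+' or '-'
    llr: float
    llr_max: float

    @property
    def end(self) -> int:
        return self.start + self.length

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end


def read_pwms(stream, pseudocount: float = 0.5,
              background: np.ndarray | None = None) -> list[PWM]:
    """Parse PWM blocks ``>NAME WIDTH`` + WIDTH rows of 4 numbers.

    Blocks end at ``<``, the next ``>`` or EOF.  Rows summing to ~1 are
    treated as probabilities and used as given (zeros floored); otherwise
    rows are counts and `pseudocount` is added per cell before normalizing.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
    lines = stream.read().splitlines()
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.startswith(">"):
            raise PwmParseError(f"line {i}: expected '>' header, got {line!r}")
        head = line[1:].split()
        if len(head) < 2:
            raise PwmParseError(f"line {i}: header needs NAME WIDTH")
        name = head[0]
        try:
            width = int(head[1])
        except ValueError as exc:
            raise PwmParseError(f"motif {name}, line {i}: bad width {head[1]!r}") from exc
        if width < 1:
            raise PwmParseError(f"motif {name}, line {i}: width must be >= 1")
        rows = []
        for k in range(width):
            if i >= len(lines) or lines[i].strip().startswith((">", "<")):
                raise PwmParseError(f"motif {name}: expected {width} rows, got {k}")
            cells = lines[i].split()
            i += 1
            if len(cells) != 4:
                raise PwmParseError(f"motif {name}, line {i}: expected 4 values")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise PwmParseError(f"motif {name}, line {i}: non-numeric cell") from exc
        if i < len(lines) and lines[i].strip() == "<":
            i += 1
        mat = np.asarray(rows, dtype=float)
        if np.any(mat < 0):
            raise PwmParseError(f"motif {name}: negative cell")
        sums = mat.sum(axis=1)
        if np.any(sums == 0):
            bad = int(np.where(sums == 0)[0][0]) + 1
            raise PwmParseError(f"motif {name}: row {bad} is all zeros")
        if np.allclose(sums, 1.0, atol=1e-3):
            probs = mat / sums[:, None]
            if np.any(probs <= 0):
                probs = np.maximum(probs, _PROB_FLOOR)
                probs /= probs.sum(axis=1, keepdims=True)
            pwms.append(PWM(name, probs, bg, pseudocount=0.0))
        else:
            mat = mat + pseudocount
            if np.any(mat.sum(axis=1) == 0):
                raise PwmParseError(f"motif {name}: zero row after pseudocount")
            probs = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(PWM(name, probs, bg, pseudocount=pseudocount))
    return pwms


def llr_score(pwm: PWM, word: str, strand: str = "+") -> float:
    """LLR of `word` for `pwm`; strand '-' scores the reverse complement."""
    if len(word) != pwm.width:
        raise ValueError(f"word length {len(word)} != PWM width {pwm.width}")
    codes = _encode(word)
    if np.any(codes < 0):
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    mat = pwm.llr_matrix if strand == "+" else pwm.rc_llr_matrix()
    return float(mat[np.arange(pwm.width), codes].sum())


def _window_scores(codes: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Sliding-window additive scores; windows containing N (-1) -> -inf."""
    w = mat.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes < 0, 0, codes)
    for k in range(w):
        scores += mat[k, safe[k:k + n_win]]
        valid &= codes[k:k + n_win] >= 0
    scores[~valid] = -np.inf
    return scores


def annotate_sites(seq: str, pwms: list[PWM],
                   threshold_frac: float = DEFAULT_THRESHOLD_FRAC) -> list[BindingSite]:
    """Annotate all windows (both strands) with LLR > threshold_frac * llr_max.

    The comparison is strict.  At the same (start, tf) only the better
    strand is kept, ties going to '+'.  Windows containing N are skipped.
    Output is sorted by start, then TF name.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    if not seq:
        raise ValueError("empty sequence")
    codes = _encode(seq)
    sites: list[BindingSite] = []
    for pwm in pwms:
        cutoff = threshold_frac * pwm.llr_max
        fwd = _window_scores(codes, pwm.llr_matrix)
        rev = _window_scores(codes, pwm.rc_llr_matrix())
        for start in range(len(fwd)):
            f, r = fwd[start], rev[start]
            best, strand = (f, "+") if f >= r else (r, "-")
            if best > cutoff:
                sites.append(BindingSite(pwm.name, start, pwm.width, strand,
                                         float(best), pwm.llr_max))
    sites.sort(key=lambda s: (s.start, s.tf))
    return sites


def permute_pwm(pwm: PWM, rng_seed: int) -> PWM:
    """Negative control: permute PWM positions (rows) uniformly under a seed.

    Per-position base composition is preserved, as is llr_max (a sum of
    per-row maxima is permutation invariant).
    """
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(pwm.width)
    return PWM(pwm.name, pwm.probs[perm], pwm.background, pwm.pseudocount)
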