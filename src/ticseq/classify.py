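"""Maximum-likelihood residue identification and sequencing-protocol figures.

Identification assigns a block of M independent current measurements to the
residue whose current distribution maximises the product of spline-PDF
densities over the block.  Because each distribution has bounded support, a
single measurement that falls outside a wrong candidate's support zeroes
that candidate's likelihood; with growing M this mechanism collapses the
misidentification error.  A likelihood tie counts as an error (Heaviside
convention H(0) = 1), which is the conservative reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "DecodedSequence",
    "ErrorCurve",
    "ProtocolReport",
    "decode_sequence",
    "error_curve",
    "ml_error",
    "protocol_report",
    "simulate_stream",
]

DEFAULT_M_GRID = (1,) + tuple(range(5, 205, 5))

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


def _validate_dists(dists):
    dists = list(dists)
    if len(dists) < 2:
        raise ValueError("need at least two candidate distributions")
    for d in dists:
        for attr in ("logpdf", "sample", "support", "residue_code"):
            if not hasattr(d, attr):
                raise TypeError(
                    "candidates must expose logpdf/sample/support/residue_code"
                )
        if not d.support[1] > d.support[0]:
            raise ValueError(f"distribution {d.residue_code} has empty support")
    return dists


def _block_loglik(dists, draws: np.ndarray) -> np.ndarray:
    """Log-likelihood of each candidate for each row of draws.

    draws has shape (n_blocks, M); returns (n_candidates, n_blocks).
    """
    flat = draws.ravel()
    out = np.empty((len(dists), draws.shape[0]))
    for yi, dy in enumerate(dists):
        out[yi] = dy.logpdf(flat).reshape(draws.shape).sum(axis=1)
    return out


def ml_error(dists, M: int, J: int, seed: int) -> float:
    """Mean maximum-likelihood misidentification error, in percent.

    For each true residue X and each of J realizations, M currents are drawn
    i.i.d. from X's distribution and every candidate Y is scored by the sum
    of log densities; the realization is an error iff some Y != X scores at
    least as high as X.  Returns 100 times the mean error over residues and
    realizations.
    """
    dists = _validate_dists(dists)
    if M < 1 or J < 1:
        raise ValueError("M and J must be >= 1")
    rng = np.random.default_rng(seed)
    err_rates = []
    for xi, dx in enumerate(dists):
        draws = dx.sample(J * M, rng).reshape(J, M)
        ll = _block_loglik(dists, draws)
        others = np.delete(ll, xi, axis=0)
        wrong = (others >= ll[xi][None, :]).any(axis=0)
        err_rates.append(wrong.mean())
    return 100.0 * float(np.mean(err_rates))


@dataclass(frozen=True)
class ErrorCurve:
    """Misidentification percentage as a function of measurements per residue."""

    m_values: tuple
    error_pct: tuple
    J: int
    seed: int

    def __post_init__(self):
        if any(not (0.0 <= e <= 100.0) for e in self.error_pct):
            raise ValueError("error percentages must lie in [0, 100]")

    def to_csv(self, path_or_buf) -> None:
        text = f"# J={self.J} seed={self.seed}\nM,error_pct\n" + "\n".join(
            f"{m},{e:.6f}" for m, e in zip(self.m_values, self.error_pct)
        ) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)


def error_curve(dists, m_values=DEFAULT_M_GRID, J: int = 1000,
                seed: int = 0) -> ErrorCurve:
    """Compute the error-versus-M curve on a grid of block sizes."""
    errs = tuple(
        ml_error(dists, int(m), J, seed + k) for k, m in enumerate(m_values)
    )
    return ErrorCurve(tuple(int(m) for m in m_values), errs, J, seed)


# ---------------------------------------------------------------------------
# protocol arithmetic


@dataclass(frozen=True)
class ProtocolReport:
    """Throughput implied by a measurement frequency and block size M.

    ``residues_per_second = floor(frequency / M)`` and the maximum pulling
    speed is one residue length per identification period, in nm/s.
    """

    measurement_frequency_hz: float
    M: int
    residue_length_A: float = 3.8
    residues_per_second: int = field(init=False)
    max_pull_speed_nm_per_s: float = field(init=False)

    def __post_init__(self):
        if self.measurement_frequency_hz <= 0 or self.residue_length_A <= 0:
            raise ValueError("frequency and residue length must be positive")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        rate = self.measurement_frequency_hz / self.M
        object.__setattr__(self, "residues_per_second", math.floor(rate))
        object.__setattr__(
            self, "max_pull_speed_nm_per_s", self.residue_length_A * 0.1 * rate
        )


def protocol_report(frequency_hz: float, M: int,
                    residue_length_A: float = 3.8) -> ProtocolReport:
    """Sequencing rate and maximum pulling speed for a measurement setup."""
    return ProtocolReport(frequency_hz, int(M), residue_length_A)


# ---------------------------------------------------------------------------
# stream decoding


@dataclass(frozen=True)
class DecodedSequence:
    codes: tuple  # three-letter residue codes, one per block
    margins: tuple  # log-likelihood margin best minus runner-up per call
    ambiguous: tuple  # True where the top likelihoods tied

    def __str__(self):
        return "-".join(self.codes)


def simulate_stream(sequence, dist_map: dict, M: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw M measurements per residue of ``sequence`` (three-letter codes)."""
    blocks = [dist_map[code].sample(M, rng) for code in sequence]
    return np.concatenate(blocks) if blocks else np.empty(0)


def decode_sequence(stream, dists, M: int) -> DecodedSequence:
    """Maximum-likelihood decoding of a current stream in blocks of M.

    The stream length must be a multiple of M (residue boundaries are
    assumed known).  Ties between top candidates are flagged ambiguous; the
    first candidate in ``dists`` order is reported for them.
    """
    stream = np.asarray(stream, dtype=float)
    if M < 1:
        raise ValueError("M must be >= 1")
    if stream.size % M != 0:
        raise ValueError(f"stream length {stream.size} is not divisible by M={M}")
    if stream.size == 0:
        return DecodedSequence((), (), ())
    dists = _validate_dists(dists)
    blocks = stream.reshape(-1, M)
    ll = _block_loglik(dists, blocks)  # (n_candidates, n_blocks)
    order = np.argsort(-ll, axis=0, kind="stable")
    best = order[0]
    second = order[1]
    codes, margins, ambiguous = [], [], []
    for b in range(blocks.shape[0]):
        l_best = ll[best[b], b]
        l_second = ll[second[b], b]
        codes.append(dists[best[b]].residue_code)
        margins.append(float(l_best - l_second))
        ambiguous.append(bool(l_best == l_second))
    return DecodedSequence(tuple(codes), tuple(margins), tuple(ambiguous))
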