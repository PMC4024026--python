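"""Exact inference on tumor take-rate tables and summary statistics.

With a handful of animals per inoculation group, differences in tumor
induction are tested with the Freeman-Halton generalization of Fisher's
exact test to r x 2 tables: conditioning on both margins, the probability
of a table is multivariate hypergeometric,

    P(T) = [prod_i C(n_i, s_i)] / C(N, S),

where row i has n_i animals and s_i successes, N animals and S successes in
total; the two-tailed p-value sums P(T) over every margin-consistent table
whose probability does not exceed that of the observed table (with a small
relative tolerance for floating-point ties). Table masses are accumulated
in log space via log-gamma to avoid factorial overflow. A Monte-Carlo
estimator over the same null serves tables too large to enumerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import InputError

__all__ = [
    "ContingencyTable",
    "MonteCarloResult",
    "SummaryStats",
    "freeman_halton_exact",
    "monte_carlo_exact",
    "take_rate",
    "summarize",
]

#: Tumor-induction outcomes per inoculation method: (label, successes, failures).
TAKE_RATE_TABLE_ROWS = (
    ("orthotopic, ultrasound-guided", 4, 0),
    ("orthotopic, unguided", 0, 4),
    ("subcutaneous flank", 0, 5),
)


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 table of (group label, successes, failures) rows."""

    rows: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise InputError("a contingency table needs at least 2 rows")
        for label, s, f in self.rows:
            if s != int(s) or f != int(f) or s < 0 or f < 0:
                raise InputError(f"row {label!r}: counts must be non-negative integers")
        if self.grand_total == 0:
            raise InputError("table grand total must be positive")

    @classmethod
    def from_counts(cls, counts, labels=None) -> "ContingencyTable":
        """Build from an iterable of (successes, failures) pairs."""
        counts = list(counts)
        labels = labels or [f"group{i + 1}" for i in range(len(counts))]
        return cls(tuple((lab, int(s), int(f)) for lab, (s, f) in zip(labels, counts)))

    @classmethod
    def from_string(cls, text: str) -> "ContingencyTable":
        """Parse an inline ``'a,b:c,d:...'`` table specification."""
        try:
            counts = [tuple(int(x) for x in row.split(",")) for row in text.split(":")]
        except ValueError as exc:
            raise InputError(f"cannot parse table spec {text!r}") from exc
        if any(len(c) != 2 for c in counts):
            raise InputError("each row must have exactly 2 comma-separated counts")
        return cls.from_counts(counts)

    @property
    def successes(self) -> np.ndarray:
        return np.array([s for _, s, _ in self.rows], dtype=int)

    @property
    def row_totals(self) -> np.ndarray:
        return np.array([s + f for _, s, f in self.rows], dtype=int)

    @property
    def grand_total(self) -> int:
        return int(self.row_totals.sum())


def _drop_zero_rows(table: ContingencyTable) -> ContingencyTable:
    kept = tuple(r for r in table.rows if r[1] + r[2] > 0)
    if len(kept) < len(table.rows):
        warnings.warn("dropping all-zero rows from the contingency table")
    if len(kept) < 2:
        raise InputError("fewer than 2 non-empty rows; the exact test is undefined")
    return ContingencyTable(kept)


def _log_mass_fn(row_totals: np.ndarray, s_total: int):
    """Log multivariate-hypergeometric mass of a success vector."""
    n_total = int(row_totals.sum())
    log_denom = gammaln(n_total + 1) - gammaln(s_total + 1) - gammaln(n_total - s_total + 1)

    def log_mass(s: np.ndarray) -> float:
        s = np.asarray(s)
        num = gammaln(row_totals + 1) - gammaln(s + 1) - gammaln(row_totals - s + 1)
        return float(num.sum() - log_denom)

    return log_mass


def _enumerate_success_vectors(row_totals: np.ndarray, s_total: int):
    """Yield every success vector consistent with the fixed margins."""
    r = len(row_totals)
    suffix = np.concatenate([np.cumsum(row_totals[::-1])[::-1][1:], [0]])
    vec = np.zeros(r, dtype=int)

    def rec(i: int, remaining: int):
        if i == r - 1:
            if remaining <= row_totals[i]:
                vec[i] = remaining
                yield vec.copy()
            return
        lo = max(0, remaining - int(suffix[i]))
        hi = min(int(row_totals[i]), remaining)
        for s in range(lo, hi + 1):
            vec[i] = s
            yield from rec(i + 1, remaining - s)

    yield from rec(0, s_total)


def freeman_halton_exact(
    table: ContingencyTable,
    tie_rel_tol: float = 1e-7,
    max_total: int = 200,
) -> float:
    """Two-tailed Freeman-Halton exact p-value for an r x 2 table.

    Enumerates all tables sharing the observed margins and sums the
    probabilities of those no more probable than the observed table
    (within ``tie_rel_tol`` relative tolerance). Tables with more than
    ``max_total`` observations are refused in favour of
    :func:`monte_carlo_exact`.
    """
    table = _drop_zero_rows(table)
    if table.grand_total > max_total:
        raise InputError(
            f"grand total {table.grand_total} exceeds {max_total}; "
            "use monte_carlo_exact for large tables"
        )
    row_totals = table.row_totals
    s_total = int(table.successes.sum())
    log_mass = _log_mass_fn(row_totals, s_total)
    log_obs = log_mass(table.successes)
    cutoff = log_obs + np.log1p(tie_rel_tol)
    masses = np.array([log_mass(s) for s in _enumerate_success_vectors(row_totals, s_total)])
    probs = np.exp(masses)
    total = probs.sum()
    if abs(total - 1.0) > 1e-12:
        raise RuntimeError(f"enumeration masses sum to {total!r}, not 1")
    p = float(probs[masses <= cutoff].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class MonteCarloResult:
    p: float
    se: float
    n_draws: int


def monte_carlo_exact(table: ContingencyTable, n_draws: int = 100_000, seed: int | None = None) -> MonteCarloResult:
    """Monte-Carlo estimate of the Freeman-Halton p-value.

    Draws success vectors from the multivariate hypergeometric null with
    the observed margins; the estimate is the fraction of draws no more
    probable than the observed table, with binomial standard error.
    """
    if n_draws < 1_000:
        raise InputError("n_draws must be >= 1000")
    table = _drop_zero_rows(table)
    row_totals = table.row_totals
    s_total = int(table.successes.sum())
    log_mass = _log_mass_fn(row_totals, s_total)
    cutoff = log_mass(table.successes) + np.log1p(1e-7)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(row_totals, s_total, size=n_draws)
    num = gammaln(row_totals + 1) - gammaln(draws + 1) - gammaln(row_totals - draws + 1)
    log_denom = (
        gammaln(table.grand_total + 1)
        - gammaln(s_total + 1)
        - gammaln(table.grand_total - s_total + 1)
    )
    log_masses = num.sum(axis=1) - log_denom
    hits = log_masses <= cutoff
    p = float(hits.mean())
    se = float(np.sqrt(p * (1 - p) / n_draws))
    return MonteCarloResult(p=p, se=se, n_draws=n_draws)


def take_rate(row) -> float:
    """Percent successes of one (successes, failures) row."""
    if len(row) == 3:  # labelled row
        _, s, f = row
    else:
        s, f = row
    if s + f <= 0:
        raise InputError("take rate undefined for an empty group")
    return 100.0 * s / (s + f)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.2f} +/- {self.sd:.2f}"


def summarize(values) -> SummaryStats:
    """Arithmetic mean and sample (n-1) standard deviation."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise InputError("summarize needs at least 2 values")
    return SummaryStats(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=int(v.size))
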