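"""Individual-based (Hurlbert) rarefaction for sampling-completeness checks.

The expected richness in a random subsample of ``n`` of the ``N`` occurrences
is the exact hypergeometric expectation

    E[S_n] = sum_i ( 1 - C(N - N_i, n) / C(N, n) )

computed in log-space so that totals up to ~1e5 occurrences pose no overflow
problem.  Curves are evaluated per stratum (hemispheric climatic zones, or
latitudinal bins of configurable width) and summarized by a terminal-slope
asymptote diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigurationError

__all__ = [
    "AbundanceVector",
    "RarefactionCurve",
    "rarefy",
    "rarefaction_curve",
    "rarefy_variance",
    "climatic_zone",
    "rarefaction_by_stratum",
    "asymptote_diagnostic",
    "curves_to_frame",
]

#: hemispheric climatic zones, 30-degree latitudinal spans
CLIMATIC_ZONES = (
    ("N polar", 60.0, 90.0),
    ("N temperate", 30.0, 60.0),
    ("N tropical", 0.0, 30.0),
    ("S tropical", -30.0, 0.0),
    ("S temperate", -60.0, -30.0),
    ("S polar", -90.0, -60.0),
)


@dataclass
class AbundanceVector:
    """Per-species occurrence counts within one stratum."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.counts = self.counts[self.counts > 0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return int(len(self.counts))


@dataclass
class RarefactionCurve:
    """Expected richness at every subsample size 1..N for one stratum."""

    stratum: str
    sizes: np.ndarray
    expected: np.ndarray
    variance: np.ndarray | None = None

    @property
    def terminal_richness(self) -> float:
        return float(self.expected[-1])


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def rarefy(abundances, n: int) -> float:
    """Exact expected richness of a random subsample of ``n`` occurrences."""
    vec = abundances if isinstance(abundances, AbundanceVector) else AbundanceVector(abundances)
    if not 1 <= n <= vec.total:
        raise ValueError(f"subsample size {n} outside [1, {vec.total}]")
    counts = vec.counts
    log_denom = _log_comb(vec.total, n)
    log_p_absent = _log_comb(vec.total - counts, n) - log_denom
    return float(np.sum(1.0 - np.exp(log_p_absent)))


def rarefy_variance(abundances, n: int) -> float:
    """Hypergeometric variance of subsample richness at size ``n``."""
    vec = abundances if isinstance(abundances, AbundanceVector) else AbundanceVector(abundances)
    if not 1 <= n <= vec.total:
        raise ValueError(f"subsample size {n} outside [1, {vec.total}]")
    counts = vec.counts
    total = vec.total
    log_denom = _log_comb(total, n)
    p_absent = np.exp(_log_comb(total - counts, n) - log_denom)
    var = np.sum(p_absent * (1.0 - p_absent))
    pair_sum = 0.0
    for i in range(len(counts)):
        joint = np.exp(
            _log_comb(total - counts[i] - counts[i + 1:], n) - log_denom
        )
        pair_sum += np.sum(joint - p_absent[i] * p_absent[i + 1:])
    return float(var + 2.0 * pair_sum)


def rarefaction_curve(
    abundances, stratum: str = "", with_variance: bool = False
) -> RarefactionCurve:
    """Full expected-richness curve over subsample sizes 1..N."""
    vec = abundances if isinstance(abundances, AbundanceVector) else AbundanceVector(abundances)
    total = vec.total
    if total < 1:
        raise ValueError("empty abundance vector")
    sizes = np.arange(1, total + 1)
    counts = vec.counts
    log_denom = _log_comb(total, sizes)
    log_num = _log_comb(
        (total - counts)[:, None], sizes[None, :]
    )
    expected = np.sum(1.0 - np.exp(log_num - log_denom[None, :]), axis=0)
    variance = None
    if with_variance:
        variance = np.array([rarefy_variance(vec, int(n)) for n in sizes])
    return RarefactionCurve(stratum, sizes, expected, variance)


def climatic_zone(latitude: float) -> str:
    """Hemispheric climatic zone of a latitude (half-open 30-degree spans)."""
    for name, low, high in CLIMATIC_ZONES:
        if low <= latitude < high or (high == 90.0 and latitude == 90.0):
            return name
    raise ValueError(f"latitude out of range: {latitude}")


def _abundances(records: pd.DataFrame) -> AbundanceVector:
    mask = (records["qualifier"] == "none") & (records["species_epithet"] != "")
    sub = records.loc[mask]
    names = sub["genus"] + " " + sub["species_epithet"]
    weights = sub["count"] if "count" in sub.columns else pd.Series(1, index=sub.index)
    counts = weights.groupby(names.to_numpy()).sum()
    return AbundanceVector(counts.to_numpy())


def rarefaction_by_stratum(
    records: pd.DataFrame,
    strata: str = "climatic_zone",
    bin_width: float = 5.0,
    with_variance: bool = False,
) -> dict[str, RarefactionCurve]:
    """One rarefaction curve per non-empty stratum of cleaned records.

    ``strata`` is ``"climatic_zone"`` (hemispheric polar / temperate /
    tropical zones) or ``"latitude_bin"`` (bins of ``bin_width`` degrees,
    keyed by their lower edge).  Empty strata are omitted.
    """
    if strata == "climatic_zone":
        keys = records["latitude"].map(climatic_zone)
    elif strata == "latitude_bin":
        edges = np.floor((records["latitude"] + 90.0) / bin_width).astype(int)
        edges = np.minimum(edges, int(round(180.0 / bin_width)) - 1)
        keys = (edges * bin_width - 90.0).astype(float).map(lambda v: f"{v:g}")
    else:
        raise ConfigurationError(f"unknown strata scheme: {strata!r}")
    curves: dict[str, RarefactionCurve] = {}
    for key, sub in records.groupby(keys.to_numpy()):
        vec = _abundances(sub)
        if vec.total < 1:
            continue
        curves[str(key)] = rarefaction_curve(vec, str(key), with_variance)
    return curves


def asymptote_diagnostic(
    curve: RarefactionCurve, threshold: float = 0.01
) -> tuple[float | None, bool | None]:
    """Terminal slope (species per occurrence over the last 10% of the
    n-range) and a flag for asymptotic tendency (slope below ``threshold``).

    Degenerate single-point curves return ``(None, None)``.
    """
    total = int(curve.sizes[-1])
    if total < 2:
        return None, None
    n0 = max(int(np.floor(0.9 * total)), 1)
    start = int(np.searchsorted(curve.sizes, n0))
    span = curve.sizes[-1] - curve.sizes[start]
    if span <= 0:
        start = len(curve.sizes) - 2
        span = curve.sizes[-1] - curve.sizes[start]
    slope = float((curve.expected[-1] - curve.expected[start]) / span)
    return slope, bool(slope < threshold)


def curves_to_frame(curves: dict[str, RarefactionCurve]) -> pd.DataFrame:
    """Long-format (stratum, n, expected_S) table of a curve collection."""
    frames = []
    for key in sorted(curves):
        curve = curves[key]
        frames.append(
            pd.DataFrame(
                {"stratum": key, "n": curve.sizes, "expected_S": curve.expected}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["stratum", "n", "expected_S"])
    return pd.concat(frames, ignore_index=True)
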