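"""Scoring and spatial statistics for 3D DNA-FISH spot tables.

Input is a table of detected FISH spots (one per nucleus, probe and
signal) together with per-nucleus geometry (centroid and effective
radius).  Pairing of the two homologous alleles is called operationally:
a nucleus is *paired* for a probe when exactly two spots of that probe
are present and their 3D distance is below a resolution threshold
(default 0.5 um, the axial step of the image stacks).  Downstream
statistics cover radial positions, radius-normalised interallelic
distances, fixed-width histograms, Tukey box-whisker summaries,
pairing-frequency categories and covariate correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Spot",
    "NucleusRecord",
    "PairingResult",
    "BoxStats",
    "score_pairing",
    "radial_distance",
    "interallelic_distance",
    "distance_histogram",
    "tukey_box_stats",
    "classify_frequency",
    "group_comparison",
    "probe_covariates",
    "pearson_correlation",
    "nuclei_from_tables",
]

PAIRING_THRESHOLD_UM = 0.5
CATEGORY_HIGH = 3.5  # percent; frequencies strictly above are "high"
CATEGORY_LOW = 2.5  # percent; frequencies strictly below are "low"


@dataclass(frozen=True)
class Spot:
    """A single FISH signal in physical coordinates (um)."""

    nucleus_id: str
    probe_id: str
    x: float
    y: float
    z: float

    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NucleusRecord:
    """One segmented nucleus with its spots.

    ``radius`` is the effective radius reported by the imaging software;
    measured spots may fall slightly outside it when the nucleus deviates
    from a sphere, so radial distances above 1 are legitimate.
    """

    nucleus_id: str
    centroid: tuple[float, float, float]
    radius: float
    spots: list[Spot] = field(default_factory=list)
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("nucleus radius must be positive")

    def spots_for(self, probe_id: str) -> list[Spot]:
        return [s for s in self.spots if s.probe_id == probe_id]


@dataclass
class PairingResult:
    """Pairing call summary for one probe, aggregated over replicates."""

    probe_id: str
    per_replicate: list[tuple[int, int]]  # (n_scored, n_paired)
    tau: float = PAIRING_THRESHOLD_UM

    @property
    def n_scored(self) -> int:
        return sum(s for s, _ in self.per_replicate)

    @property
    def n_paired(self) -> int:
        return sum(p for _, p in self.per_replicate)

    @property
    def frequency(self) -> float:
        """Pooled pairing frequency, percent."""
        if self.n_scored == 0:
            return 0.0
        return 100.0 * self.n_paired / self.n_scored

    @property
    def replicate_frequencies(self) -> list[float]:
        return [100.0 * p / s if s else 0.0 for s, p in self.per_replicate]


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-whisker summary: hinges, fenced whiskers, outliers."""

    median: float
    lower_hinge: float
    upper_hinge: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.upper_hinge - self.lower_hinge


def score_pairing(
    nuclei: Sequence[NucleusRecord],
    probe_id: str,
    tau: float = PAIRING_THRESHOLD_UM,
) -> PairingResult:
    """Call pairing per nucleus and aggregate frequencies per replicate.

    A nucleus is scored if it carries at least one spot of the probe.  It
    is called paired iff it carries exactly two spots of the probe and
    their 3D Euclidean distance is strictly below ``tau`` (um).  Nuclei
    with three or more spots are scored but never paired — extra signals
    disqualify the call.
    """
    if not nuclei:
        raise ValueError("empty nucleus list")
    probes_seen = {s.probe_id for nuc in nuclei for s in nuc.spots}
    if probe_id not in probes_seen:
        raise KeyError(f"probe {probe_id!r} absent from all nuclei")
    per_rep: dict[int, list[int]] = {}
    for nuc in nuclei:
        spots = nuc.spots_for(probe_id)
        if not spots:
            continue
        scored, paired = per_rep.setdefault(nuc.replicate, [0, 0])
        scored += 1
        if len(spots) == 2:
            d = float(np.linalg.norm(spots[0].coords() - spots[1].coords()))
            if d < tau:
                paired += 1
        per_rep[nuc.replicate] = [scored, paired]
    reps = [tuple(per_rep[k]) for k in sorted(per_rep)]
    return PairingResult(probe_id=probe_id, per_replicate=reps, tau=tau)


def radial_distance(spot: Spot, nucleus: NucleusRecord) -> float:
    """Distance of a spot from the nuclear centroid, as fraction of radius.

    Values above 1 are returned unchanged; they occur when the nucleus is
    not a perfect sphere.
    """
    d = float(np.linalg.norm(spot.coords() - np.asarray(nucleus.centroid, float)))
    return d / nucleus.radius


def interallelic_distance(spot_a: Spot, spot_b: Spot, nucleus: NucleusRecord) -> float:
    """3D distance between two spots, normalised to the nuclear radius."""
    d = float(np.linalg.norm(spot_a.coords() - spot_b.coords()))
    return d / nucleus.radius


def distance_histogram(
    values: Sequence[float],
    bin_width: float = 0.7,
    centers: Sequence[float] = (0.0, 0.7, 1.4, 2.1),
) -> tuple[np.ndarray, int]:
    """Histogram of normalised distances in fixed-width bins.

    Bins are ``[center - w/2, center + w/2)`` for each listed center
    (defaults: four bins of width 0.7r centred at 0, 0.7, 1.4 and 2.1).
    Values falling in no bin are counted in the overflow tally, so counts
    plus overflow always equal the input size.
    """
    vals = np.asarray(values, dtype=float)
    half = bin_width / 2.0
    counts = np.zeros(len(centers), dtype=int)
    assigned = np.zeros(vals.shape, dtype=bool)
    for i, c in enumerate(centers):
        in_bin = (vals >= c - half) & (vals < c + half) & ~assigned
        counts[i] = int(in_bin.sum())
        assigned |= in_bin
    overflow = int((~assigned).sum())
    return counts, overflow


def tukey_box_stats(values: Sequence[float]) -> BoxStats:
    """Tukey box-whisker statistics.

    Hinges are Tukey hinges: medians of the lower and upper halves of the
    sorted data, with the overall median included in both halves when n
    is odd.  Whiskers extend to the most extreme data points within
    1.5 * IQR of the hinges; points beyond the fences are outliers.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = vals.size
    if n == 0:
        raise ValueError("empty input")
    median = float(np.median(vals))
    half = (n + 1) // 2  # includes median in both halves when n odd
    lower_hinge = float(np.median(vals[:half]))
    upper_hinge = float(np.median(vals[n - half :]))
    iqr = upper_hinge - lower_hinge
    lo_fence = lower_hinge - 1.5 * iqr
    hi_fence = upper_hinge + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return BoxStats(
        median=median,
        lower_hinge=lower_hinge,
        upper_hinge=upper_hinge,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in outliers),
    )


def classify_frequency(frequency: float) -> Literal["high", "medium", "low"]:
    """Assign a pairing-frequency category.

    high: strictly above 3.5%; low: strictly below 2.5%; medium: the
    closed interval [2.5%, 3.5%].
    """
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    if frequency > CATEGORY_HIGH:
        return "high"
    if frequency < CATEGORY_LOW:
        return "low"
    return "medium"


def group_comparison(
    groups: Sequence[Sequence[float]],
    method: Literal["t_test", "anova_bonferroni"] | None = None,
) -> dict:
    """Compare distance/frequency groups.

    Two groups: two-sided unpaired t-test.  Three or more: one-way ANOVA
    followed by all pairwise two-sided t-tests with Bonferroni-adjusted
    p-values (``min(1, raw * n_comparisons)``).  Two groups that are both
    constant with equal means get t=0, p=1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if method is None:
        method = "t_test" if len(arrays) == 2 else "anova_bonferroni"

    def _ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if a.std() == 0 and b.std() == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            return float("inf"), 0.0
        t, p = stats.ttest_ind(a, b)
        return float(t), float(p)

    if method == "t_test":
        if len(arrays) != 2:
            raise ValueError("t_test requires exactly two groups")
        t, p = _ttest(arrays[0], arrays[1])
        return {"method": "t_test", "t": t, "p": p}

    f, p_anova = stats.f_oneway(*arrays)
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        t, raw = _ttest(arrays[i], arrays[j])
        pairwise.append(
            {"groups": (i, j), "t": t, "p_raw": raw, "p_adj": min(1.0, raw * m)}
        )
    return {
        "method": "anova_bonferroni",
        "f": float(f),
        "p_anova": float(p_anova),
        "pairwise": pairwise,
    }


def _union_length(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"malformed interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def probe_covariates(
    probe: tuple[int, int],
    gene_intervals: Sequence[tuple[int, int]],
    read_positions: Sequence[int],
) -> tuple[float, int]:
    """Gene density and expression count for one probe interval.

    Gene density is the fraction of the probe interval covered by the
    union of gene intervals; expression count is the number of read
    positions falling inside the probe.  All intervals are 0-based,
    half-open, on the probe's chromosome.
    """
    start, end = probe
    if start >= end:
        raise ValueError("probe interval must have start < end")
    covered = 0
    for g_start, g_end in _union_length(gene_intervals):
        covered += max(0, min(end, g_end) - max(start, g_start))
    pos = np.asarray(read_positions, dtype=int)
    count = int(((pos >= start) & (pos < end)).sum())
    return covered / (end - start), count


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with two-sided p-value from the t transform."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def nuclei_from_tables(
    nucleus_table: pd.DataFrame, spot_table: pd.DataFrame
) -> list[NucleusRecord]:
    """Assemble NucleusRecords from a nucleus table and a spot table.

    Expected columns — nuclei: nucleus_id, cx, cy, cz, radius_um and
    optionally replicate; spots: nucleus_id, probe_id, x_um, y_um, z_um.
    """
    required_nuc = {"nucleus_id", "cx", "cy", "cz", "radius_um"}
    required_spot = {"nucleus_id", "probe_id", "x_um", "y_um", "z_um"}
    if missing := required_nuc - set(nucleus_table.columns):
        raise ValueError(f"nucleus table missing columns: {sorted(missing)}")
    if missing := required_spot - set(spot_table.columns):
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    spots_by_nuc: dict[str, list[Spot]] = {}
    for row in spot_table.itertuples(index=False):
        spots_by_nuc.setdefault(str(row.nucleus_id), []).append(
            Spot(str(row.nucleus_id), str(row.probe_id), row.x_um, row.y_um, row.z_um)
        )
    nuclei = []
    for row in nucleus_table.itertuples(index=False):
        nid = str(row.nucleus_id)
        nuclei.append(
            NucleusRecord(
                nucleus_id=nid,
                centroid=(row.cx, row.cy, row.cz),
                radius=row.radius_um,
                spots=spots_by_nuc.get(nid, []),
                replicate=int(getattr(row, "replicate", 0)),
            )
        )
    return nuclei
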