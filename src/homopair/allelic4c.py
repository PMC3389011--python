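"""Allele-specific linear 4C-Seq quantification.

A linear 4C assay anchors one restriction fragment (the bait) and reads
out, via ligation-junction sequencing, every fragment (prey) found
ligated to it.  In an inter-strain hybrid (here C57BL/6J x SD7, a
congenic strain carrying distal chromosome 7 from Mus spretus) a subset
of restriction fragments carries strain-distinguishing SNPs readable
from the junction, so bait-prey products can be assigned to parental
alleles and contacts between the two homologues ("trans-allelic")
separated from ordinary cis contacts and from heterologous trans
contacts.

This module provides the computational chain: in-silico digestion of the
two haplotype genomes, classification of fragments by allelic
informativeness, a simplified SNP-based allele caller for junction
reads, unique-position deduplication, and the three windowed summaries
used to quantify contacts (100 kb cis profile, 200 kb trans-allelic hit
rate, 1.4 Mb genome-wide trans comparison with Tukey outlier flagging).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .fish_stats import BoxStats, tukey_box_stats

__all__ = [
    "FragmentMap",
    "WindowSummary",
    "HIT_KEY",
    "digest_genome",
    "classify_informative",
    "assign_allele",
    "map_prey_fragment",
    "build_hits",
    "dedupe_positions",
    "cis_window_profile",
    "trans_allelic_rate",
    "genomewide_trans_summary",
]

DEFAULT_SITE = "AAGCTT"  # HindIII-style six-cutter
DEFAULT_CUT_OFFSET = 1
DEFAULT_READ_LENGTH = 50

ALLELES = ("B6", "SD7")

#: columns identifying a unique 4C association after deduplication
HIT_KEY = ["chrom", "prey_position", "bait_allele", "prey_allele"]


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    Fragments are 0-based half-open and tile every chromosome without
    gaps or overlaps.  Fragment ids are ``"<chrom>:<index>"``.
    """

    table: pd.DataFrame  # columns: chrom, start, end, fragment_id

    def __post_init__(self) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._lengths: dict[str, int] = {}
        for chrom, sub in self.table.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise ValueError(f"fragment starts not increasing on {chrom}")
            if not (starts[1:] == ends[:-1]).all() or starts[0] != 0:
                raise ValueError(f"fragments do not tile chromosome {chrom}")
            self._starts[str(chrom)] = starts
            self._lengths[str(chrom)] = int(ends[-1])

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    def chrom_length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is None:
            return len(self.table)
        return self._starts[chrom].size

    def fragment_bounds(self, fragment_id: str) -> tuple[str, int, int]:
        chrom, idx = fragment_id.rsplit(":", 1)
        i = int(idx)
        starts = self._starts[chrom]
        end = starts[i + 1] if i + 1 < starts.size else self._lengths[chrom]
        return chrom, int(starts[i]), int(end)

    def locate(self, chrom: str, position: int) -> str:
        """Fragment id containing ``position`` (half-open convention)."""
        if chrom not in self._starts:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= position < self._lengths[chrom]:
            raise IndexError(f"position {position} outside {chrom}")
        i = bisect_right(self._starts[chrom], position) - 1
        return f"{chrom}:{i}"

    def locate_many(self, chroms: Sequence[str], positions: Sequence[int]) -> list[str]:
        out = []
        chroms = np.asarray(chroms)
        positions = np.asarray(positions)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            pos = positions[mask]
            if pos.size and (pos.min() < 0 or pos.max() >= self._lengths[str(chrom)]):
                raise IndexError(f"position outside {chrom}")
            idx = np.searchsorted(self._starts[str(chrom)], pos, side="right") - 1
            orig = np.flatnonzero(mask)
            out.extend((int(orig[k]), f"{chrom}:{i}") for k, i in enumerate(idx))
        out.sort()
        return [fid for _, fid in out]


def digest_genome(
    sequences: Mapping[str, str],
    site: str = DEFAULT_SITE,
    cut_offset: int = DEFAULT_CUT_OFFSET,
) -> FragmentMap:
    """In-silico restriction digestion of one haplotype genome.

    Cuts at ``occurrence_start + cut_offset`` for every exact occurrence
    of the recognition ``site``; fragments run between consecutive cuts
    and chromosome ends, zero-length fragments are dropped.  Digest each
    haplotype separately: SNPs may create or destroy sites.
    """
    site = site.upper()
    if not site or set(site) - set("ACGT"):
        raise ValueError(f"recognition site must be non-empty over ACGT: {site!r}")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the site")
    pattern = re.compile(f"(?={re.escape(site)})")  # overlap-safe scan
    rows = []
    for chrom, seq in sequences.items():
        seq = str(seq).upper()
        cuts = [m.start() + cut_offset for m in pattern.finditer(seq)]
        bounds = [0] + cuts + [len(seq)]
        starts = [b for i, b in enumerate(bounds[:-1]) if b < bounds[i + 1]]
        ends = [b for i, b in enumerate(bounds[1:]) if bounds[i] < b]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "fragment_id": [f"{chrom}:{i}" for i in range(len(starts))],
                }
            )
        )
    return FragmentMap(pd.concat(rows, ignore_index=True))


def classify_informative(
    fragments: FragmentMap,
    snps: pd.DataFrame,
    read_length: int = DEFAULT_READ_LENGTH,
) -> pd.DataFrame:
    """Classify fragments by whether junction reads can reveal their allele.

    A fragment is *stringent* when at least one substitution SNP lies
    within ``read_length`` bases of either fragment end, so a read
    sequenced from a ligation junction covers it; *weak* when it contains
    SNPs only beyond that range; *uninformative* otherwise.

    ``snps`` needs columns chrom, pos (0-based), ref, alt.  Returns a
    DataFrame with fragment_id, chrom, start, end, n_snps, class.
    """
    frag = fragments.table.copy()
    frag["n_snps"] = 0
    frag["near_end"] = False
    by_chrom = {c: s.sort_values("pos") for c, s in snps.groupby("chrom")}
    n_snps = np.zeros(len(frag), dtype=int)
    near = np.zeros(len(frag), dtype=bool)
    for row in frag.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        inside = pos[(pos >= row.start) & (pos < row.end)]
        n_snps[row.Index] = inside.size
        if inside.size:
            near[row.Index] = bool(
                ((inside < row.start + read_length) | (inside >= row.end - read_length)).any()
            )
    frag["n_snps"] = n_snps
    frag["near_end"] = near
    frag["class"] = np.where(
        frag["near_end"], "stringent", np.where(frag["n_snps"] > 0, "weak", "uninformative")
    )
    return frag.drop(columns="near_end")


def assign_allele(
    read_bases: str,
    aligned_interval: tuple[str, int, int],
    snps: pd.DataFrame,
) -> Literal["B6", "SD7", "ambiguous", "uninformative"]:
    """Call the parental allele of a read from the SNPs it covers.

    The read is assumed aligned without indels, so base ``i`` of the read
    sits at genomic position ``start + i``.  If every covered SNP base
    matches one haplotype that allele is called; covering SNPs that match
    different haplotypes, or a base matching neither, gives *ambiguous*;
    covering no SNP gives *uninformative*.  B6 is the reference
    haplotype (VCF ref), SD7 the alternate.
    """
    chrom, start, end = aligned_interval
    if start < 0 or end < start:
        raise ValueError("malformed aligned interval")
    if end - start != len(read_bases):
        raise ValueError("interval length does not match read length")
    sub = snps[(snps["chrom"] == chrom) & (snps["pos"] >= start) & (snps["pos"] < end)]
    if sub.empty:
        return "uninformative"
    matched: set[str] = set()
    for rec in sub.itertuples():
        base = read_bases[rec.pos - start].upper()
        if base == rec.ref.upper():
            matched.add("B6")
        elif base == rec.alt.upper():
            matched.add("SD7")
        else:
            return "ambiguous"
    if len(matched) == 1:
        return next(iter(matched))
    return "ambiguous"


def assign_alleles(reads: pd.DataFrame, snps: pd.DataFrame) -> np.ndarray:
    """Bulk allele calling for aligned reads (same rule as assign_allele).

    ``reads`` needs columns chrom, read_start, read_end, sequence.  Uses
    per-chromosome sorted SNP arrays with binary search, so it scales to
    large read sets.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in snps.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[str(chrom)] = (
            sub["pos"].to_numpy(),
            sub["ref"].str.upper().to_numpy(),
            sub["alt"].str.upper().to_numpy(),
        )
    calls = np.empty(len(reads), dtype=object)
    for k, rec in enumerate(reads.itertuples(index=False)):
        entry = by_chrom.get(rec.chrom)
        if entry is None:
            calls[k] = "uninformative"
            continue
        pos, ref, alt = entry
        lo = np.searchsorted(pos, rec.read_start, side="left")
        hi = np.searchsorted(pos, rec.read_end, side="left")
        if lo == hi:
            calls[k] = "uninformative"
            continue
        matched: set[str] = set()
        call = None
        for j in range(lo, hi):
            base = rec.sequence[pos[j] - rec.read_start].upper()
            if base == ref[j]:
                matched.add("B6")
            elif base == alt[j]:
                matched.add("SD7")
            else:
                call = "ambiguous"
                break
        if call is None:
            call = next(iter(matched)) if len(matched) == 1 else "ambiguous"
        calls[k] = call
    return calls


def map_prey_fragment(
    position: tuple[str, int], fragments: FragmentMap
) -> str:
    """Fragment id containing a genomic position (half-open fragments).

    A position equal to a fragment end belongs to the next fragment.
    """
    chrom, pos = position
    return fragments.locate(chrom, pos)


def build_hits(
    reads: pd.DataFrame,
    fragments: FragmentMap,
    bait_fragment_id: str,
) -> pd.DataFrame:
    """Turn allele-called prey reads into classified association hits.

    ``reads`` needs columns chrom, prey_position, bait_allele,
    prey_allele (values B6/SD7/ambiguous/uninformative).  Relation is
    *cis* when the prey lies on the bait chromosome and its allele is
    not distinguishable from the bait's or matches it; *trans_allelic*
    when the prey lies on the bait chromosome but carries the other
    haplotype's alleles; *trans_chromosomal* for any other chromosome.
    """
    bait_chrom, _, _ = fragments.fragment_bounds(bait_fragment_id)
    hits = reads.copy()
    hits["prey_fragment_id"] = fragments.locate_many(
        hits["chrom"].tolist(), hits["prey_position"].tolist()
    )
    on_bait_chrom = hits["chrom"] == bait_chrom
    other = {"B6": "SD7", "SD7": "B6"}
    is_trans_allelic = on_bait_chrom & (
        hits["prey_allele"] == hits["bait_allele"].map(other)
    )
    hits["relation"] = np.where(
        ~on_bait_chrom,
        "trans_chromosomal",
        np.where(is_trans_allelic, "trans_allelic", "cis"),
    )
    return hits


def dedupe_positions(hits: pd.DataFrame) -> pd.DataFrame:
    """Count each position only once per (bait allele, prey allele) stratum.

    Retains the first hit per unique (chrom, prey_position, bait_allele,
    prey_allele) key and returns hits in stable genome-coordinate order.
    Idempotent.
    """
    if hits.empty:
        return hits.copy()
    out = hits.drop_duplicates(subset=HIT_KEY, keep="first")
    return out.sort_values(
        ["chrom", "prey_position", "bait_allele", "prey_allele"], kind="stable"
    ).reset_index(drop=True)


@dataclass
class WindowSummary:
    """Per-window counts or rates over a fixed half-open tiling from 0."""

    window_size: int
    table: pd.DataFrame  # columns: chrom, start, end, value [, n_stringent]

    def total(self) -> float:
        return float(self.table["value"].sum())


def _window_index(pos: np.ndarray, window: int) -> np.ndarray:
    return pos // window


def _tile(chrom: str, length: int, window: int) -> pd.DataFrame:
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def cis_window_profile(
    hits: pd.DataFrame,
    fragments: FragmentMap,
    bait_chrom: str,
    window: int = 100_000,
) -> WindowSummary:
    """Unique cis positions per 100 kb window on the bait chromosome.

    ``hits`` must be deduplicated cis hits; the sum over windows equals
    the number of unique cis positions.
    """
    tiles = _tile(bait_chrom, fragments.chrom_length(bait_chrom), window)
    tiles["value"] = 0
    if not hits.empty:
        idx = _window_index(hits["prey_position"].to_numpy(), window)
        counts = pd.Series(idx).value_counts()
        tiles.loc[counts.index, "value"] = counts.to_numpy()
    return WindowSummary(window_size=window, table=tiles)


def trans_allelic_rate(
    hits: pd.DataFrame,
    informative: pd.DataFrame,
    fragments: FragmentMap,
    bait_chrom: str,
    window: int = 200_000,
) -> WindowSummary:
    """Trans-allelic hit rate per 200 kb window on the bait chromosome.

    Per window: the number of distinct stringently informative fragments
    with at least one trans-allelic hit, divided by the number of
    stringent fragments in the window (a fragment counts at most once no
    matter how many hits it received).  Windows without stringent
    fragments carry a missing rate (NaN), distinguishing "nothing could
    be detected" from "nothing was detected".  Fragments are assigned to
    the window containing their start.
    """
    tiles = _tile(bait_chrom, fragments.chrom_length(bait_chrom), window)
    stringent = informative[
        (informative["chrom"] == bait_chrom) & (informative["class"] == "stringent")
    ]
    n_str = np.zeros(len(tiles), dtype=int)
    if not stringent.empty:
        counts = pd.Series(
            _window_index(stringent["start"].to_numpy(), window)
        ).value_counts()
        n_str[counts.index] = counts.to_numpy()
    tiles["n_stringent"] = n_str

    n_hit = np.zeros(len(tiles), dtype=int)
    if not hits.empty:
        stringent_ids = set(stringent["fragment_id"])
        hit_frags = hits.loc[
            hits["prey_fragment_id"].isin(stringent_ids), "prey_fragment_id"
        ].unique()
        if hit_frags.size:
            starts = stringent.set_index("fragment_id").loc[hit_frags, "start"]
            counts = pd.Series(
                _window_index(starts.to_numpy(), window)
            ).value_counts()
            n_hit[counts.index] = counts.to_numpy()
    with np.errstate(invalid="ignore"):
        tiles["value"] = np.where(n_str > 0, n_hit / np.maximum(n_str, 1), np.nan)
    return WindowSummary(window_size=window, table=tiles)


def genomewide_trans_summary(
    trans_hits: pd.DataFrame,
    fragments: FragmentMap,
    homologous_window: tuple[str, int, int],
    window: int = 1_400_000,
) -> tuple[WindowSummary, BoxStats, pd.DataFrame]:
    """Genome-wide comparison of trans association counts per 1.4 Mb window.

    Counts unique trans associations (the hits must be deduplicated) per
    half-open window tiled from 0 on every chromosome, computes Tukey
    box statistics over the window counts and flags windows beyond the
    upper fence as outliers.  The designated homologous window — the
    tiling window containing the midpoint of ``homologous_window`` — is
    reported with its count and outlier status in the flags table.
    """
    tiles = pd.concat(
        [_tile(c, fragments.chrom_length(c), window) for c in fragments.chromosomes],
        ignore_index=True,
    )
    tiles["value"] = 0
    if not trans_hits.empty:
        counts = pd.DataFrame(
            {
                "chrom": trans_hits["chrom"].to_numpy(),
                "w": trans_hits["prey_position"].to_numpy() // window,
            }
        ).value_counts()
        tiles["value"] = [
            int(counts.get((c, s // window), 0))
            for c, s in zip(tiles["chrom"], tiles["start"])
        ]
    box = tukey_box_stats(tiles["value"].to_numpy())
    upper_fence = box.upper_hinge + 1.5 * box.iqr
    tiles["outlier_high"] = tiles["value"] > upper_fence

    h_chrom, h_start, h_end = homologous_window
    mid = (h_start + h_end) // 2
    mid = min(max(mid, 0), fragments.chrom_length(h_chrom) - 1)
    flags = tiles[
        (tiles["chrom"] == h_chrom)
        & (tiles["start"] <= mid)
        & (mid < tiles["end"])
    ].copy()
    flags["homologous"] = True
    return WindowSummary(window_size=window, table=tiles), box, flags
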