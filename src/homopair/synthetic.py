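"""Synthetic data generators for the FISH and 4C pipelines.

Everything the analysis consumes can be generated here with known ground
truth: two-haplotype genomes with strain-distinguishing SNPs, linear 4C
read sets built from a cis/homologous-trans/background mixture with
distance decay, nuclei with radially biased FISH spots and a known true
pairing probability, and jointly correlated probe covariates.  All
generators are deterministic given a `numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allelic4c import ALLELES, DEFAULT_READ_LENGTH, FragmentMap
from .nuclear_model import RadialModel, _place_batch, _sample_limits_batch

__all__ = [
    "FourCGeneratorConfig",
    "NucleiGeneratorConfig",
    "ProbePreset",
    "DEFAULT_RADIAL_MODEL",
    "PRESETS",
    "make_haplotype_genome",
    "simulate_4c_reads",
    "simulate_nuclei",
    "simulate_probe_covariates",
]

BASES = np.array(list("ACGT"))

#: radial placement shared by the FISH presets: signals avoid the very
#: centre and the extreme periphery, as interphase loci typically do
DEFAULT_RADIAL_MODEL = RadialModel(mu_c=0.4, sigma_c=0.1, mu_p=0.95, sigma_p=0.05)


@dataclass(frozen=True)
class ProbePreset:
    """A named FISH probe condition: true pairing probability + radial bias."""

    probe_id: str
    pairing_probability: float
    radial_model: RadialModel = DEFAULT_RADIAL_MODEL


#: study-condition presets: the imprinting-control-region probe pairs in
#: about 4% of E13.5 liver nuclei, twice as often as the myc control
PRESETS: dict[str, ProbePreset] = {
    "kvdmr_liver": ProbePreset("KvDMR", 0.04),
    "myc_liver": ProbePreset("myc", 0.02),
}


# ---------------------------------------------------------------------------
# genomes


def make_haplotype_genome(
    n_chroms: int = 20,
    length: int = 2_000_000,
    snp_rate: float = 0.005,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Two haplotype genomes differing by random substitution SNPs.

    Haplotype B6 is uniform random over ACGT; SD7 carries independent
    substitutions at ``snp_rate`` per base.  Returns
    ``({"B6": {chrom: seq}, "SD7": {...}}, snps)`` where ``snps`` has
    columns chrom, pos (0-based), ref, alt with ref != alt everywhere.
    """
    if not 0 <= snp_rate <= 0.1:
        raise ValueError("snp_rate must lie in [0, 0.1]")
    if rng is None:
        rng = np.random.default_rng()
    b6: dict[str, str] = {}
    sd7: dict[str, str] = {}
    snp_rows = []
    for i in range(n_chroms):
        chrom = f"chr{i + 1}"
        ref = rng.integers(0, 4, size=length)
        alt = ref.copy()
        pos = np.flatnonzero(rng.random(length) < snp_rate)
        # substitute with one of the three other bases, uniformly
        alt[pos] = (ref[pos] + rng.integers(1, 4, size=pos.size)) % 4
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        b6[chrom] = codes[ref].tobytes().decode("ascii")
        sd7[chrom] = codes[alt].tobytes().decode("ascii")
        snp_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": BASES[ref[pos]],
                    "alt": BASES[alt[pos]],
                }
            )
        )
    snps = pd.concat(snp_rows, ignore_index=True)
    return {"B6": b6, "SD7": sd7}, snps


# ---------------------------------------------------------------------------
# 4C reads


@dataclass(frozen=True)
class FourCGeneratorConfig:
    """Mixture model for linear 4C ligation products.

    Each read picks a bait allele fairly and then a prey category:
    cis (weight ``1 - beta - gamma``) with distance decay
    ``(|d| + d0) ** -alpha`` around the bait, homologous trans (weight
    ``beta``) with the same decay around the bait's position on the
    other haplotype, or background trans (weight ``gamma``) uniform over
    all fragments on other chromosomes.
    """

    bait_chrom: str = "chr1"
    bait_position: int = 1_000_000
    alpha: float = 1.5
    d0: float = 10_000.0
    beta: float = 0.10
    gamma: float = 0.02
    n_reads: int = 100_000
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("decay exponent alpha must be positive")
        if not (0 <= self.beta <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("beta and gamma must lie in [0, 1]")
        if self.beta + self.gamma > 1:
            raise ValueError("beta + gamma must not exceed 1")


def _decay_weights(
    fragments: FragmentMap, chrom: str, center: int, alpha: float, d0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment indices on ``chrom`` and decay weights around ``center``."""
    sub = fragments.table[fragments.table["chrom"] == chrom]
    mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
    w = (np.abs(mids - center) + d0) ** -alpha
    return sub.index.to_numpy(), w / w.sum()


def simulate_4c_reads(
    config: FourCGeneratorConfig,
    fragments: dict[str, FragmentMap],
    haplotypes: dict[str, dict[str, str]],
    rng: np.random.Generator,
    emit_sequences: bool = True,
) -> pd.DataFrame:
    """Simulate allele-resolved 4C junction reads with ground truth.

    ``fragments`` maps each allele to the fragment map of its haplotype.
    Each read is sequenced from one (randomly chosen) end of its prey
    fragment, inward, for up to ``read_length`` bases.  Returns a truth
    table with columns read_id, bait_allele, category, prey_allele,
    chrom, prey_position, prey_fragment_id, read_start, read_end and
    (when ``emit_sequences``) the read bases taken from the prey
    haplotype, with optional uniform substitution errors.
    """
    for allele in ALLELES:
        if allele not in fragments:
            raise KeyError(f"fragment map for allele {allele} missing")
        if fragments[allele].n_fragments() < 2:
            raise ValueError("degenerate fragment map (< 2 fragments)")

    n = config.n_reads
    bait_allele = rng.choice(ALLELES, size=n)
    category = rng.choice(
        ["cis", "homologous_trans", "background_trans"],
        size=n,
        p=[1 - config.beta - config.gamma, config.beta, config.gamma],
    )

    # per-allele precomputation: decay weights on the bait chromosome and
    # the uniform background over other chromosomes
    decay: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    background: dict[str, np.ndarray] = {}
    bait_fid: dict[str, str] = {}
    for allele in ALLELES:
        fmap = fragments[allele]
        bait_fid[allele] = fmap.locate(config.bait_chrom, config.bait_position)
        idx, w = _decay_weights(
            fmap, config.bait_chrom, config.bait_position, config.alpha, config.d0
        )
        decay[allele] = (idx, w)
        background[allele] = fmap.table.index[
            fmap.table["chrom"] != config.bait_chrom
        ].to_numpy()

    prey_allele = np.empty(n, dtype=object)
    frag_row = np.empty(n, dtype=int)
    other = {"B6": "SD7", "SD7": "B6"}
    bg_mask = category == "background_trans"
    prey_allele[bg_mask] = rng.choice(ALLELES, size=int(bg_mask.sum()))
    for ba in ALLELES:
        for cat in ("cis", "homologous_trans"):
            mask = (bait_allele == ba) & (category == cat)
            m = int(mask.sum())
            if m == 0:
                continue
            pa = ba if cat == "cis" else other[ba]
            idx, w = decay[pa]
            if cat == "cis":
                # exclude the bait fragment itself (self-ligation)
                keep = idx != _row_of(fragments[pa], bait_fid[pa])
                w_cis = w[keep] / w[keep].sum()
                frag_row[mask] = rng.choice(idx[keep], size=m, p=w_cis)
            else:
                frag_row[mask] = rng.choice(idx, size=m, p=w)
            prey_allele[mask] = pa
    for allele in ALLELES:
        mask = bg_mask & (prey_allele == allele)
        m = int(mask.sum())
        if m:
            frag_row[mask] = rng.choice(background[allele], size=m)

    rows = []
    from_end = rng.random(n) < 0.5
    for allele in ALLELES:
        amask = prey_allele == allele
        sub = fragments[allele].table.loc[frag_row[amask]]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lengths = np.minimum(config.read_length, ends - starts)
        fe = from_end[amask]
        read_start = np.where(fe, ends - lengths, starts)
        rows.append(
            pd.DataFrame(
                {
                    "read_index": np.flatnonzero(amask),
                    "bait_allele": bait_allele[amask],
                    "category": category[amask],
                    "prey_allele": allele,
                    "chrom": sub["chrom"].to_numpy(),
                    "prey_position": read_start,
                    "prey_fragment_id": sub["fragment_id"].to_numpy(),
                    "read_start": read_start,
                    "read_end": read_start + lengths,
                }
            )
        )
    truth = (
        pd.concat(rows, ignore_index=True)
        .sort_values("read_index", kind="stable")
        .reset_index(drop=True)
    )
    truth["read_id"] = [f"read_{i}" for i in truth["read_index"]]
    truth = truth.drop(columns="read_index")

    if emit_sequences:
        seqs = []
        for rec in truth.itertuples():
            seq = haplotypes[rec.prey_allele][rec.chrom][rec.read_start : rec.read_end]
            seqs.append(seq)
        if config.error_rate > 0:
            seqs = _apply_errors(seqs, config.error_rate, rng)
        truth["sequence"] = seqs
    return truth


def _row_of(fmap: FragmentMap, fragment_id: str) -> int:
    return int(fmap.table.index[fmap.table["fragment_id"] == fragment_id][0])


def _apply_errors(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    base_to_i = {b: i for i, b in enumerate(BASES)}
    out = []
    for seq in seqs:
        arr = np.array([base_to_i[b] for b in seq])
        hit = rng.random(arr.size) < rate
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        out.append("".join(BASES[arr]))
    return out


# ---------------------------------------------------------------------------
# nuclei


@dataclass(frozen=True)
class NucleiGeneratorConfig:
    """FISH imaging emulation: replicate panels of spherical nuclei.

    Defaults mirror the scored panels: 4 technical replicates of 300
    nuclei, 5 um nuclear radius, spots quantized to 0.5 um z-planes.
    The paired-partner offset (0.4 um) stays below the 0.5 um scoring
    threshold so the true pairing probability is recoverable.
    """

    probes: tuple[ProbePreset, ...] = (PRESETS["kvdmr_liver"],)
    n_replicates: int = 4
    nuclei_per_replicate: int = 300
    radius_um: float = 5.0
    paired_offset_um: float = 0.4
    z_step_um: float = 0.5

    def __post_init__(self) -> None:
        for probe in self.probes:
            if not 0 <= probe.pairing_probability <= 1:
                raise ValueError("pairing probability must lie in [0, 1]")
        if self.paired_offset_um >= 0.5:
            raise ValueError("paired offset must stay below the 0.5 um threshold")


def simulate_nuclei(
    config: NucleiGeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate nuclei, FISH spots and ground-truth pairing labels.

    Per nucleus and probe: with the probe's pairing probability, place
    spot A under the probe's radial model and its partner at a uniform
    lateral offset (< paired_offset_um) on the same optical section —
    a merged, pairable annotation sits within one z-plane; otherwise
    place both spots independently under the radial model.  Coordinates
    are converted to um and z is quantized to the imaging plane spacing.

    Returns (nucleus_table, spot_table, truth_table).
    """
    nuc_rows = []
    spot_rows = []
    truth_rows = []
    n_total = config.n_replicates * config.nuclei_per_replicate
    for rep in range(config.n_replicates):
        for i in range(config.nuclei_per_replicate):
            nid = f"r{rep}_n{i}"
            centroid = rng.uniform(20.0, 200.0, size=3)
            centroid[2] = _quantize(centroid[2], config.z_step_um)
            nuc_rows.append(
                {
                    "nucleus_id": nid,
                    "cx": centroid[0],
                    "cy": centroid[1],
                    "cz": centroid[2],
                    "radius_um": config.radius_um,
                    "replicate": rep,
                }
            )
            for probe in config.probes:
                paired = rng.random() < probe.pairing_probability
                c, p = _sample_limits_batch(probe.radial_model, 1, rng)
                a = _place_batch(c, p, rng)[0] * config.radius_um
                if paired:
                    b = a + _uniform_disc(config.paired_offset_um, rng)
                else:
                    c2, p2 = _sample_limits_batch(probe.radial_model, 1, rng)
                    b = _place_batch(c2, p2, rng)[0] * config.radius_um
                for spot in (a, b):
                    spot_rows.append(
                        {
                            "nucleus_id": nid,
                            "probe_id": probe.probe_id,
                            "x_um": centroid[0] + spot[0],
                            "y_um": centroid[1] + spot[1],
                            "z_um": _quantize(centroid[2] + spot[2], config.z_step_um),
                        }
                    )
                truth_rows.append(
                    {
                        "nucleus_id": nid,
                        "probe_id": probe.probe_id,
                        "replicate": rep,
                        "paired": paired,
                    }
                )
    assert len(nuc_rows) == n_total
    return (
        pd.DataFrame(nuc_rows),
        pd.DataFrame(spot_rows),
        pd.DataFrame(truth_rows),
    )


def _quantize(z: float, step: float) -> float:
    return round(z / step) * step


def _uniform_disc(radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform offset within a lateral disc (z component zero)."""
    r = radius * np.sqrt(rng.random())
    theta = rng.uniform(0, 2 * np.pi)
    return np.array([r * np.cos(theta), r * np.sin(theta), 0.0])


# ---------------------------------------------------------------------------
# covariates


def simulate_probe_covariates(
    n: int,
    target_r: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Jointly correlated expression counts and pairing frequencies.

    Draws latent bivariate-normal pairs with correlation ``target_r``
    and maps them to non-negative expression counts (mildly log-normal,
    so the sample Pearson r of the outputs converges to the target) and
    pairing frequencies clipped to [0, 10] percent.
    """
    if not -1 < target_r < 1:
        raise ValueError("|target_r| must be below 1")
    if n < 4:
        raise ValueError("need n >= 4 probes")
    cov = np.array([[1.0, target_r], [target_r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    expression = np.round(np.exp(5.0 + 0.3 * z[:, 0])).astype(int)
    frequency = np.clip(5.0 + 1.5 * z[:, 1], 0.0, 10.0)
    if np.unique(expression).size == 1:
        raise RuntimeError("degenerate draw: constant expression output")
    return pd.DataFrame(
        {
            "probe_id": [f"probe_{i}" for i in range(n)],
            "expression_count": expression,
            "pairing_frequency": frequency,
        }
    )
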