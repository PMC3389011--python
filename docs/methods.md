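# Methods

This note documents the models implemented in `homopair`, the defaults
chosen where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## FISH pairing score

A nucleus enters the denominator for a probe when it carries at least
one detected spot of that probe; it is called *paired* iff it carries
exactly two spots whose 3D Euclidean distance is strictly below the
threshold τ, and no further spots. Defaults and rationale:

* **τ = 0.5 µm.** The axial step of the image stacks the score emulates
  is 0.5 µm, which bounds the resolution of spot separation; two signals
  closer than this merge into one annotation. The inequality is strict —
  a distance of exactly 0.5 µm scores unpaired.
* **≥ 3 spots ⇒ unpaired.** Extra signals make the two-allele
  interpretation unsafe, so such nuclei are scored but never paired.
  Lowering τ can therefore only reduce the paired count (monotonicity,
  enforced by tests).
* **Denominator.** All nuclei with ≥ 1 spot of the probe. Whether the
  original panels excluded signal-free nuclei is not documented; this
  choice reproduces "events per imaged panel" while tolerating synthetic
  dropouts, and exclusions are visible in the per-replicate tables.
* **Distances** are isotropic Euclidean in physical µm. The axial
  quantisation of real stacks is a property of the *data* (the synthetic
  generator quantises z to 0.5 µm planes); the metric does not re-weight
  axes.

Pairing frequencies are classified high (> 3.5 %), medium (the closed
interval 2.5–3.5 %) or low (< 2.5 %); both boundary values fall in
"medium".

Box-whisker summaries use **Tukey hinges** (medians of the lower and
upper halves, the overall median included in both halves when n is odd),
whiskers to the most extreme points within 1.5 × IQR of the hinges, and
points beyond the fences as outliers. This convention, not
linear-interpolation quartiles, is fixed throughout (including the
genome-wide 4C summary) and is cross-checked against a brute-force
enumeration oracle in the tests.

Interallelic-distance histograms default to four bins of width 0.7 (in
units of nuclear radius) centred at 0, 0.7, 1.4 and 2.1, each bin
[c − 0.35, c + 0.35); values outside every bin go to an overflow tally
so counts always conserve the sample size.

Radial distances are distance-to-centroid divided by the nucleus'
effective radius and are **not clipped at 1**: segmented nuclei are not
perfect spheres, so measured spots may fall outside the nominal radius.
The radius itself is taken as given input; no shape estimation is done.

## Radial exclusion-limit null model

The null model for interallelic distances places signals in a unit
sphere under a *central* exclusion limit c (minimum radial position) and
a *peripheric* limit p (maximum radial position), each drawn per signal
from its own normal distribution. Numerical choices:

* **In-shell law: volume-uniform.** The model places signals "at random"
  within the permitted shell; the natural meaning for a spatial null is
  uniform per unit volume, via inverse CDF on r³. (A radius-uniform law
  would concentrate mass towards the centre.)
* **Clipping and rejection.** Draws are clipped to [0, 1]; pairs with
  c ≥ p are rejected and redrawn, preserving the two stated normals as
  marginals conditioned on validity. Rejection is vectorised with
  adaptive oversampling and aborts with a clear error when the
  acceptance region is practically unreachable (e.g. µ_c ≫ µ_p with tiny
  spreads).
* **Simulation uses a perfect unit sphere** even though observed radials
  may exceed 1; observed values are clipped to 1 for fitting only.
* **Fitting** is an exhaustive grid search minimising the two-sample
  Kolmogorov–Smirnov distance between n_sim simulated radials per
  candidate and the observed set (the original matching was done by
  eye; a KS grid search makes it reproducible). Default grid: µ over
  [0, 1] in 11 steps, σ over [0, 0.2] in 5 steps, for both limits, with
  unreachable candidates skipped; default n_sim = 600. Ties break by
  smaller σ_c + σ_p, then grid order.
* **Identifiability.** The peripheric parameters are well identified:
  most shell volume sits near the outer limit. The central parameters
  are weakly identified — a central limit of 0.2 under a peripheric
  limit of 0.9 excludes only ≈ 1 % of the shell volume, so grids members
  differing in (µ_c, σ_c) can be equivalent in law at the resolution a
  600-observation sample affords. Fits should be read as a matched
  *distribution*, not as point estimates of all four parameters; the
  test suite asserts recovery accordingly (KS criterion, peripheric
  parameters, and distributional equivalence).

Null interallelic distances are Euclidean distances between two
independently placed signals (models may differ per allele), default
sample size 600 to match the observed panels. Sanity anchors: the fully
unconstrained model reproduces the uniform-ball closed forms E[r] = 3/4
and E[d] = 36/35.

## Allele-specific 4C quantification

* **Digestion.** Exact-match scan for the recognition site with a cut
  offset inside the site; fragments tile each chromosome half-open from
  0, zero-length fragments dropped. The assay's enzyme is configurable;
  the default `AAGCTT` (offset 1) is a standard 3C six-cutter and all
  downstream logic is site-agnostic. Both haplotypes are digested
  independently, since SNPs can create or destroy sites.
* **Stringently informative fragments.** A fragment is stringent when a
  substitution SNP lies within one read length (default 50 bp) of either
  fragment end — the region a junction read can actually cover; a SNP
  only deeper inside makes the fragment *weak*; otherwise
  *uninformative*. This operational rule stands in for the original
  pipeline's unpublished stringency criteria.
* **Allele calling.** Reads are assumed aligned without indels (the
  synthetic reads carry their true coordinates; no aligner is bundled —
  read mapping is external tooling). Every covered SNP must agree on one
  haplotype; disagreement or a base matching neither haplotype gives
  *ambiguous*, no covered SNP gives *uninformative*. B6 is the VCF
  reference haplotype, SD7 the alternate.
* **Relations.** A called hit is *cis* when the prey lies on the bait
  chromosome without evidence of the other haplotype (this keeps
  ambiguous and uninformative preys in the total cis counts, where they
  are indistinguishable from cis), *trans-allelic* when the prey lies on
  the bait chromosome but carries the other haplotype's alleles, and
  *trans-chromosomal* otherwise.
* **Deduplication.** One hit per (chromosome, position, bait allele,
  prey allele); stratifying by both alleles keeps the maternal- and
  paternal-bait profiles independent. Order-stable and idempotent, so
  window counts are invariant under read permutation.
* **Windows** tile each chromosome half-open from coordinate 0 (the
  anchor is otherwise arbitrary and fixed here for reproducibility):
  100 kb for the cis profile, 200 kb for trans-allelic rates, 1.4 Mb for
  the genome-wide trans comparison. In the 200 kb rate, a stringent
  fragment counts at most once regardless of hit multiplicity, and a
  window with no stringent fragments is reported *missing* (NaN, no bar)
  — "could not detect" is distinct from "detected nothing". Fragments
  belong to the window containing their start. The genome-wide summary
  flags windows beyond the upper Tukey fence and reports the designated
  homologous window (the tiling window containing the supplied
  interval's midpoint, clamped to the chromosome) separately.

## Synthetic data: what it emulates

* **Genomes.** Haplotype B6 is uniform random sequence; SD7 differs by
  independent substitutions at 0.005/bp by default, emulating the
  elevated divergence of a *M. spretus* congenic region against
  C57BL/6J that makes fragments allele-informative. Every difference is
  recorded as a VCF substitution record.
* **4C reads.** Each read draws a bait allele fairly and a prey category
  from {cis: 1 − β − γ, homologous trans: β, background trans: γ}. Cis
  and homologous-trans preys follow a shifted power-law distance decay
  (|d| + d₀)^(−α) around the bait (resp. its position on the other
  haplotype), defaults α = 1.5, d₀ = 10 kb — the decay of real 3C
  contact profiles is not parameterised in a published form, so these
  are one fixed, plausible choice. Background preys are uniform over
  fragments on other chromosomes. Defaults β = 0.10, γ = 0.02 put the
  generator in the homologous-enrichment regime (β ≫ γ) in which
  trans-allelic contacts concentrate on the homologous window; the true
  ratio in tissue is unknown and these weights are illustrative, not
  calibrated. Reads are sequenced inward from a randomly chosen fragment
  end for up to one read length; an optional uniform substitution error
  rate is available (default 0: allele-calling exactness is a test
  anchor).
* **Nuclei.** Four replicates of 300 nuclei, radius 5 µm, one
  radially-biased placement model per probe (default: shell between
  ~0.4 and ~0.95 of the radius). With probability q the two spots of a
  probe are a true pair: the first is placed under the radial model and
  the partner at a uniform lateral offset < 0.4 µm **on the same optical
  section**. A merged microscope annotation implies the two signals sit
  within one focal plane, and keeping the pair coplanar means the 0.5 µm
  z-quantisation (applied to all spots) cannot push a true pair past the
  scoring threshold — otherwise axial rounding would silently unpair
  ~30 % of true pairs and the generating q would not be recoverable.
  Unpaired spots are placed independently. Chance proximity of unpaired
  spots adds a small positive bias to recovered frequencies (~0.1–0.3 %
  at the default geometry); the test suite measures it rather than
  assuming it away. Presets: `kvdmr_liver` q = 4 %, `myc_liver` q = 2 %
  (the imprinted-region probe pairs about twice as often as the myc
  control).
* **Covariates.** Probe-level expression counts and pairing frequencies
  are derived from a latent bivariate normal with a target correlation;
  the expression map is mildly log-normal (σ = 0.3) so the sample
  Pearson r of the emitted values converges to the target.

What the generators do **not** emulate: image segmentation and spot
detection (inputs are coordinate tables), non-spherical nuclei,
cell-cycle structure, chromatin-state-dependent 3C bias, mappability
and realistic sequencing error profiles, and any aligner behaviour.
Passing recovery tests therefore validate the *analysis chain* under
its stated assumptions, not the upstream measurement process.

## Problem sizes and determinism

Every stochastic component takes an explicit `numpy.random.Generator`;
pipelines resolve their configuration (defaults filled in) to a YAML
file next to their outputs, and a given configuration and seed
reproduce outputs byte-identically. The test suite and the acceptance
script run on deliberately small problem instances — 4 × 300-nucleus
panels, a 20-chromosome × 2 Mb toy genome at 10⁵ reads, 10⁶ draws for
the geometry closed forms — chosen so the full suite completes in a few
minutes while keeping every statistical check at its stated power.

## Known limitations

* The stringency rule for informative fragments is an operational
  surrogate; the original pipeline's exact criteria are unpublished.
* The central exclusion-limit parameters of the radial model are only
  weakly identified from realistic sample sizes (see above).
* The homologous-window flag depends on the Tukey fence of the window
  count distribution; with few chromosomes or heavily truncated tiling
  windows the fence is driven by window-size heterogeneity.
* `assign_allele` assumes indel-free alignment; real hybrid genomes
  would need indel-aware coordinates (liftover) before calling.
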