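# Methods

## Glycan model

Glycans are modelled at composition level: counts of Hex, HexNAc, dHex
(fucose), NeuAc and optional phosphate, derived deterministically from
the shorthand grammar (`M<k>[F]`, `GlcNAc<k>[F]`, `[F]A<n>[G<g>][S<s>]`,
optional isomer suffix `a`/`b`). Linkage detail is reduced to the three
terminal features the downstream statistics need: terminal β1,2-GlcNAc
(agalactosylated, asialo complex antennae only), terminal α1,3-arm
mannose (Man3+ cores with exactly two core GlcNAc), and core fucose
(any dHex ≥ 1; antennary fucose is disallowed in this model). Isomer
suffixes are labels only.

Classification is total on the grammar-reachable space: chitobiose
core-type (HexNAc ≤ 2, no Hex), oligomannosidic (HexNAc 2, Hex ≥ 5, no
fucose), paucimannosidic (HexNAc 2, Hex 1–4), complex/hybrid
(HexNAc ≥ 3). `M4` is classed paucimannosidic. A fucosylated
oligomannosidic composition (e.g. `M5F`) is deliberately an error: core
fucosylation requires a FUT8-competent (processed) intermediate, which
the oligomannosidic state by definition has not reached. The same logic
drives the two enzyme rules: Endo H cleaves oligomannosidic species
only, and every non-oligomannosidic species counts as a potential FUT8
substrate. Phosphomannose is representable (+79.96633 Da) but excluded
from classification; it occurs only at trace levels on this protein.

Monosaccharide residue masses (5-decimal monoisotopic and average) ship
as a versioned TSV; free-glycan masses add one water, Asn-conjugated
masses are pure residue sums.

## Protein model

Sequences use 1-based precursor (UniProt) numbering with the signal
peptide included. The canonical human myeloperoxidase precursor
(P05164, 745 aa) and its chain table (signal 1–48, propeptide 49–164,
light/α 165–278, heavy/β 279–745) ship with the package. Sequon
detection is the N-X-S/T motif with X ≠ Pro; the precursor has six
sequons, of which Asn139 (propeptide) is removed on maturation — the
`mature_sequons` view filters to annotated mature chains and returns
the five β-chain sites. Polypeptide masses come from elemental
composition via pyteomics; an independent biopython computation is used
as a cross-check in the tests. The full-length α-chain computes to
12 881.4 Da average; observed intact α-chain envelopes sit slightly
lower because of C-terminal truncation variants, which this package
treats as user-supplied modification factors rather than inferring
them. Modifications are (name, targets, delta, max copies) records:
Met/Trp oxidation +15.99491, Tyr chlorination +33.96103, heme b
+616.177 (the covalent ester/sulfonium linkage correction of mature MPO
heme is not hard-coded; the heme mass is a parameter), disulfides
−2.01565 per bridge, the interprotomer Cys319–Cys319 bridge counted
once per diprotomer.

## Site profiles and the Endo H transform

Within each site × replicate, relative abundance = AUC / ΣAUC over all
reported forms including the non-glycosylated peptide (`unoccupied`).
No ionisation-efficiency correction is applied; occupancy is therefore
an AUC-share estimate and biased to the extent that glycosylated and
non-glycosylated peptides ionise differently. Profiles are compared by
Pearson correlation on the union of glycoform keys (absent species =
0, minimum three keys, zero-variance vectors rejected). Group
comparisons use Student's t-tests (two-sided unpaired by default;
one-sided and paired variants available); p-values are reported raw,
with Benjamini–Hochberg available but off by default. Replicates
aggregate as mean ± SD.

The Endo H transform remaps every sensitive (oligomannosidic) glycoform
onto the single-GlcNAc stub (`GlcNAc1`; a hypothetical fucosylated
sensitive form would map to `GlcNAc1F`), sums merged abundances and
leaves resistant species and `unoccupied` unchanged. It is idempotent
and conserves normalisation.

## Processing metrics

The metric definitions are this package's explicit formalisation (the
sets are stated nowhere as formulas in the source literature):

- conversion = occupied non-oligomannosidic / occupied;
- core fucosylation = fucosylated / FUT8-eligible (undefined, not 0,
  when no eligible substrate exists);
- β1,2-GlcNAc removal = (paucimannosidic + chitobiose core) / (those +
  agalactosylated asialo complex); Gal/NeuAc-extended species are no
  longer hexosaminidase substrates and sit outside both sets;
- α1,3-Man removal = Man1/Man2-type / Man1–3-type within the
  paucimannosidic pool, fucosylated and afucosylated pooled.

All metrics ignore `unoccupied`, are invariant to common rescaling and
to merging same-category species, and return "undefined" (NaN in
tables) on an empty denominator. The accessibility association pools
accessible-site replicate values (Asn323/483/729) and t-tests each
occluded site (Asn355/391) against the pool.

## Solvent accessibility

Shrake–Rupley with a deterministic golden-spiral lattice (default 960
points, no RNG): an atom's accessible fraction is the share of points
on its probe-expanded sphere outside every neighbour's expanded sphere,
scaled by 4π(r+p)². The probe defaults to 5 Å — a large probe chosen to
report accessibility to glycan-processing enzymes rather than water.
Radii are element-based (C 1.87, N 1.65, O 1.40, S 1.85 Å …; shipped
TSV), hydrogens follow the united-atom convention, unknown elements
fall back to 1.80 Å with a warning. Relative accessibility normalises a
residue's area by the same residue's atoms computed in isolation with
identical probe/lattice — a fully exposed reference that avoids
needing modelled tripeptide coordinates; a caller-supplied reference
table can override it. Accuracy: ≤ 1 % vs the analytic two-sphere cap
solution at 4000 points; ≤ 2 % vs a Monte-Carlo surface oracle and an
independent Shrake–Rupley implementation on random clusters. Toy
structures (pseudo-globular clusters with surface/core marker residues,
translated dimers) make occlusion claims testable against closed-form
geometry.

## Proteoform assembly

Weights assume site independence (the central simplifying assumption:
per-site quantitation contains no co-occurrence information) and
independence of modification factors; both protomers of a diprotomer
draw from the same pool (no assembly selectivity). Diprotomer weights
follow the unordered-pair rule (2·p_i·p_j off-diagonal, p_i² diagonal;
they sum to 1), masses subtract two hydrogens for the interprotomer
disulfide. Pruning below θ (default 10⁻⁶) is reported as lost weight.
Masses are average-scale by default (isotopic structure is unresolved
at ~144 kDa). Envelopes are rendered by binning variant weights onto a
uniform grid (spacing ≤ FWHM/12) and convolving with a Gaussian kernel;
apex ties break toward lower mass. Envelope comparison reports the apex
offset, the overlap coefficient (integral of the pointwise minimum of
the two unit-area traces) and 1 %-of-max spans.

## Mass photometry

One-dimensional EM with quantile-spaced initial means, pooled-SD
initial widths and uniform weights; convergence at log-likelihood gain
< 10⁻⁸ or 500 iterations; the full log-likelihood trajectory is kept so
monotonicity is assertable. An SD floor of 1 % of the component mean
prevents variance collapse (single-particle histograms have
instrument-limited width). Components map to species by nearest
expected mass within ±15 %; the apparent K_d uses
K_d = f²C/(1−f) and requires a user-supplied total particle
concentration C (9.49 nM is the back-computed value at which a 7 %
monomer fraction corresponds to a ~50 pM constant; the true acquisition
concentration is an input, not a constant of nature).

## Synthetic data

Site profiles draw from Dirichlet distributions whose concentration
parameters mirror the measured sparsity (1–3 dominant species per
site: truncated species at Asn323/483, oligomannosidic at Asn355/391,
largely unoccupied Asn729); explicit true profiles can override the
draw for recovery tests. Measurement noise is lognormal per species per
replicate (σ = 0.2 default) on top of a lognormal site-level intensity
scalar; three technical replicates by default. Particle masses draw
from a two-component Gaussian mixture (73/144 kDa, SD 6 kDa, weights
0.07/0.93, n = 5000). What the generator does **not** emulate:
ionisation-efficiency differences between glycoforms, correlated
(non-independent) site occupancy, chromatographic interference,
mass-dependent photometry calibration error. Tests passing on this
model therefore validate the arithmetic and statistics of the pipeline,
not instrument systematics.

## Numerical and design choices

- Deterministic everything: seeded `numpy.random.default_rng` for all
  stochastic generators; the SASA lattice and EM initialisation are
  RNG-free, so reruns are byte-identical (checked via manifest hashes).
- Degenerate inputs are first-class: all-zero AUC groups, zero-variance
  correlation vectors, empty metric denominators, f ∈ {0, 1} in the K_d
  formula and empty variant lists raise or flag rather than returning
  silent zeros.
- Problem sizes in the analysis scripts (≈10³ protomer / 3×10⁵
  diprotomer variants, n = 5000 particles, 60-atom toy structures) were
  chosen to exercise the combinatorics at the same order of magnitude
  as the real protein while keeping every script in seconds on a
  laptop.

## Limitations

Composition-level glycan logic cannot distinguish arm isomers; the
occupancy estimate inherits AUC-share bias; enumeration assumes site
independence, which overstates proteoform diversity if glycoforms
co-occur nonrandomly; the apparent K_d is conditional on the supplied
acquisition concentration; relative accessibilities use an
isolated-residue reference, so values are not numerically comparable to
tripeptide-normalised scales (rankings and occluded/accessible calls
are robust to this choice).
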