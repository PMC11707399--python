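# Methods

## Scope and data model

The package assesses megabenthos communities sampled by bottom trawl along
an estuarine gradient. Its containers are site × species density matrices
(abundance in ind·km⁻², biomass in kg·km⁻²) with explicit site and species
registries, a site metadata table (position, distance to the river mouth,
cruise and group labels), a sites × parameters environment table (the
15-parameter registry Tem, Sa, pH, Tu, Depth, Chl, NO₃, NO₂, NH₄, PO₄,
SiO₃, DIN, N/P, Si/N, Si/P), and a rooted Newick phylogeny whose tips cover
the species registry. All tables are plain delimited text; networks are
GraphML; reports are JSON.

## Pre-analysis standardization

Catches are converted to densities by the swept-area method: density =
catch / (net width × tow distance). When a site holds repeated tows the
counts and swept areas are summed before division (ratio of sums). The
mean-of-ratios alternative weights short and long tows equally and is
biased for unequal tow lengths; ratio of sums is the effort-weighted
estimator, and the choice only matters when tow geometry varies within a
site. Severely damaged specimens keep their count but take the mean wet
mass of undamaged conspecifics; species represented only by damaged
individuals cannot be imputed and are excluded from the biomass table with
a report entry. Biotic and environmental values are log(x+1) transformed
before correlation, ordination and dissimilarity work; the base is
configurable (default 10) and recorded in outputs, since no downstream
conclusion should depend on it.

## Index definitions and conventions

*Alpha.* Proportions are taken over species with positive density.
Shannon H′ uses log base 2 by default (the common convention in
marine-survey reports); Pielou J′ = H′/log₂S shares the base, so J′ ∈ [0,1]
regardless of it. Margalef d = (S−1)/ln N uses the natural log of total
density; densities are used as provided rather than converted to counts,
and the output records this. Simpson is reported as diversity D = 1 − Σp²
alongside D′ = 1/Σp². Undefined cases (empty unit; J′ with one species)
are NaN, never zero.

*Phylogenetic.* PD is the branch-length sum of the minimal rooted subtree
spanning the present tips (a single tip contributes its root path). MPD
and MNTD are presence-based by default — typical trawl practice, and robust
to the heavy-tailed densities trawls produce — with an abundance-weighted
MPD behind a flag. NRI standardizes MPD against a tip-label-shuffle null
(equivalently: redraw the same richness uniformly from all tips), 999
draws by default, seeded; if the null has zero spread (e.g. every tip
present) NRI is exactly 0 when the observed MPD equals the null and NaN
otherwise. The PSV family is computed from the tip correlation matrix
C_ij = V_ij/√(V_ii·V_jj), with V_ij the shared root-to-tip branch length
(depth of the most recent common ancestor, obtained as
(depth_i + depth_j − d_ij)/2 from the patristic matrix). Dividing by the
geometric mean of tip depths makes the matrix well defined on
non-ultrametric trees and reduces to the classical form on ultrametric
ones. PSV = 1 − mean off-diagonal C; PSR = PSV·S;
PSE = (N² − mᵀCm)/(N² − Σm²) for abundance vector m (equals PSV at equal
abundances); PSC = 1 − mean over tips of their largest off-diagonal
correlation. Species absent from the tree are dropped fail-soft and the
coverage fraction is recorded on the output.

*Networks.* Per community group (≥ 4 sites), species occurring in at least
20 % of the group's sites are correlated pairwise (Spearman on log₁₀(x+1)
densities); edges keep |ρ| ≥ 0.6 with Benjamini–Hochberg adjusted p < 0.05.
All four thresholds are configurable and embedded in the graph artifact, as
co-occurrence networks are notoriously sensitive to them. Topology:
d = 2E/N; l = mean shortest path over the largest component (unweighted);
c = mean local clustering with degree-<2 nodes contributing 0; m = the
modularity of the best partition found — by exhaustive partition
enumeration for networks of ≤ 10 nodes (greedy agglomeration cannot be
guaranteed optimal and small survey networks make exactness affordable) and
by deterministic greedy agglomeration on |ρ| weights beyond that.

*Stability.* ICV = mean/sd (ddof 1) of per-site total density; zero
variance yields NaN, not infinity. Cohesion: each species' connectedness is
the mean of its positive (resp. negative) correlations with all other
species; a site's C_pos/C_neg weight connectedness by relative abundance,
and C_total = C_pos + |C_neg|; group values are means over member sites. No
null-model correction is applied by default (the observed-correlation
variant); the correlation source is the same Spearman-on-log convention as
the networks. AVD excludes zero-variance species and averages |z| over the
remaining sites × species cells. Robustness removes ⌊fraction·N⌋ nodes
(uniformly at random, averaged over seeded repetitions, or the dominant
set) and counts a survivor as extinct when it retains no surviving
neighbour; because removing an isolated node cannot isolate others, one
pass suffices. Vulnerability is the maximum over nodes of the relative drop
in global efficiency (mean inverse shortest path over ordered pairs, 0 for
disconnected pairs) when that node is deleted, each reduced efficiency
taken over the remaining node set.

## Entropy-weight composites

Each composite synthesizes one 8-index block: C-diversity and C-phyl over
sites, C-stability over community groups (it contains group-level network
statistics, so sites cannot be its alternatives). Min–max normalization
orients every index as benefit (r = (x−min)/range) or cost
(r = (max−x)/range); NRI and C_neg enter as magnitudes, |NRI| read as cost
(departure from the null in either direction) and |C_neg| as benefit
(negative associations buffer communities). AVD defaults to cost — the
classical higher-variation-is-less-stable reading — and Vulnerability to
cost; everything else is benefit. The orientation table is fully
user-overridable, and deliberately so: in the simulated flood scenario the
damaged communities show *higher* AVD (per-cell patchy damage disperses
density profiles), supporting the cost reading, but sparse heavily-thinned
matrices can also depress mean |z|, so the sign of AVD's association with
stability is data-dependent and worth checking per study. Weights follow
the entropy rule p_ij = r_ij/Σᵢr_ij (0/0 → 0, 0·ln 0 = 0, no epsilon
smoothing — exactness makes the constant-column limit clean),
e_j = −Σp ln p / ln n, w_j = (1−e_j)/Σ(1−e_k); a constant column has
maximal entropy and weight 0. Scores are Σ_j w_j r_ij ∈ [0,1]. Missing
cells are imputed as the column minimum and flagged; fully missing columns
are dropped. With few alternatives the min–max step stretches even
near-constant columns to [0,1], so composites over 3–4 groups are noisy —
scoring all cruise-by-group communities together (7 alternatives in the
default study) anchors the ranges and is the recommended use.

## Structure and association stages

Dissimilarity is Bray–Curtis on log(x+1) densities (Jaccard available);
the similarity language of survey reports is read as 1 − Bray–Curtis.
UPGMA (group-average linkage) clusters units with a flat cut at
dissimilarity 1 − similarity_cut (default similarity 0.30), or at a fixed
group count. PCoA Gower-centers the squared dissimilarities and
eigendecomposes; Bray–Curtis is a semimetric, so negative eigenvalues
occur — they are reported in full, excluded from the proportion-explained
denominator, and coordinates span the positive axes. PERMANOVA uses the
standard pseudo-F from within/between squared distances with
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) over seeded label permutations;
group comparisons along individual ordination axes use Kruskal–Wallis.
Dominance Y = (pooled relative abundance) × (occurrence frequency) is
computed within each group, with the conventional Y ≥ 0.02 flag.

Group tests are Kruskal–Wallis with two-sided Wilcoxon rank-sum post hocs,
BH-adjusted by default ("none" mirrors unadjusted reporting). The Mantel
test correlates lower triangles (Spearman default, 999 seeded
permutations); the environmental side is Euclidean on z-scored parameters.
RDA z-scores predictors, centers the log-transformed response, fits
multivariate least squares and eigendecomposes the fitted matrix; axis
proportions are relative to total response variance, so constrained +
residual variance reconstructs the total exactly (this matches the
variance conventions of the standard constrained-ordination
implementations). Predictors exceeding n−1 raise an error; exactly
collinear ones are dropped with a report.

## Synthetic estuarine scenario

The generator exists to give every stage an input with known structure.
One latent gradient drives everything: salinity rises with distance d from
the river mouth as S_max(1 − e^(−d/τ)) with S_max = 32 PSU and τ = 30 km,
while turbidity, silicate, nitrogen and chlorophyll decay on the same
scale and the stoichiometric ratios are derived from their components.
τ is chosen so the community transition produced by the niche model falls
at the 30 km mark that defines the estuarine/marine truth labels —
consistent with the diluted-water extent of a large river plume. Sites are
laid out deterministically: 60 sites at power-spaced distances (denser near
the mouth, as surveys sample), alternating north/south flanks so both
flanks always hold estuarine sites.

Species respond to salinity through Gaussian niches
A_j·exp(−(sal−μ_j)²/2w_j²): 30 % are estuarine specialists
(μ ~ U(5,16) PSU), the rest marine (μ ~ U(26,33)); widths w ~ U(2,3.5) are
niche breadths on the latent axis (which proxies the whole correlated
environmental complex, hence narrower than raw salinity tolerances); peak
densities are log-normal around 3000 ind·km⁻². Realized densities multiply
by log-normal noise (σ = 0.8, the overdispersion scale of trawl catches)
and truncate below a 1 ind·km⁻² detection floor, producing realistic
sparsity. Biomass multiplies abundance by a log-normal species mean mass,
keeping S_b informative beyond S_a. A three-cruise study (spring low-flow
IA, summer low-flow IB, artificial-flood IC) shares one phylogeny (Yule,
rate 1) and niche table; cruises redraw environment and community noise
and scale overall catch by 0.47/1.0/0.67 — the seasonal pattern of reported
mean survey abundances — with cruise-specific bottom temperatures.

The flood pulse hits the estuarine sites of one flank (southern by
default): salinity drops 8 PSU (clipped at 0), silicate triples (ratios
rederived), and the fauna is damaged patchily — every affected site ×
species cell draws an independent multiplier f^E with E ~ Exponential(1),
where f is the damage factor (default 0.3) for non-specialists and the
attenuated 0.5 + 0.5f for specialists, which ride out the freshening but
are still disturbed by deposition. The geometric-mean multiplier equals
the configured factor; damage 1 is an exact identity, damage 0 removes
every non-specialist while specialists persist. Per-cell (rather than
per-site) patchiness is deliberate: it disintegrates the damaged fauna's
co-occurrence structure the way a deposition event does, instead of
imprinting a shared disturbance gradient that would *create* correlations.

What the generator does not emulate: hydrodynamics and sediment transport,
temporal autocorrelation between cruises beyond the flood switch, species
interactions (niches are independent given salinity), phylogenetic signal
in niches (specialists are assigned at random on the tree), and
zero-inflation beyond the detection floor. Passing recovery tests
therefore shows the pipeline detects gradient-structured composition and
patchy disturbance at survey-realistic noise; it does not certify
behaviour under interaction-driven or phylogenetically conserved community
assembly.

## Determinism and numerics

Every stochastic step (NRI null, network robustness, permutation tests,
the generator) takes a seed; the pipeline derives stage seeds as
(master + crc32(stage name)) mod 2³¹, so adding a stage never perturbs
another's draws, and a fixed config reproduces outputs byte-identically.
Degenerate inputs resolve explicitly: zero-variance ICV/AVD and sub-minimum
communities give NaN with a reason, empty networks are valid artifacts
with a warning, all-zero sites carry zero distance to each other, and the
NRI degenerate null is resolved by tolerance (1e−10 relative) rather than
exact float equality.

## Problem sizes used in validation

The shipped tests validate network statistics against exhaustive
enumeration on 200 random graphs of 4–8 nodes (robustness against the
exact all-subsets average at 2000 Monte-Carlo draws), calibrate PERMANOVA,
Mantel and Kruskal–Wallis type-I error with 500 null simulations each at
99 permutations, and run the recovery checks on 20 seeded replicates of
the default 60-site × 150-species three-cruise flood scenario with
200-draw robustness estimates — sizes at which the exhaustive references
are exact and the Monte-Carlo error is far below the effect sizes being
detected.

## Known limitations

Cohesion lacks the taxa-shuffle null correction some stability work
applies (flagged for a future flag); the co-occurrence networks use rank
correlation, not compositional methods, so strong gradients inflate edge
density in small site groups; entropy-weight composites over few
alternatives are range-amplified (see above); and the RDA reports axis
proportions and scores but no permutation test of the constrained
fraction.
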