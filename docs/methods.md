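# Methods

## The trial and its model

The package analyzes a line × tester factorial: l candidate inbred
lines each crossed to t = 2 testers of known, complementary heterotic
groups, the l·t testcrosses grown with check hybrids in a resolvable
incomplete-block (alpha-lattice) design with r replications over e
environments (location-year combinations), separately under two
research conditions (parasite-infested and non-infested strips). The
plot model for a quantitative trait is

    y = μ + env + rep(env) + block(env×rep) + g_line + g_tester
        + s_line×tester + (g×env terms) + ε

with hybrids treated as fixed and environment and the design strata as
random. The ANOVA uses sequential (Type I) least-squares sums of
squares in exactly that model order, computed as residual-SS
differences of nested fits via an SVD projection (rank-safe for the
exactly collinear dummy blocks). The incomplete-block adjustment is the
sequential block-within-rep term — the intrablock analysis — not a
recovery-of-interblock-information lattice analysis; consequently in
very small designs the block term can absorb degrees of freedom that a
complete-block layout would assign to treatment interactions (the test
suite checks closed-form df in a complete-block configuration and
df-accounting identities in the lattice).

F-ratios divide each factor's mean square by its factor × environment
mean square when that term is fitted, by the residual otherwise;
environment is tested against rep(env). Significance is coded
*, **, ***, † at 0.05, 0.01, 0.001, 0.0001.

## Effects and their errors

GCA/SCA/HSGCA come from raw testcross cell means pooled over reps and
environments (not BLUEs), so the centering identities — ΣGCA = 0 per
factor, SCA rows and columns sum to zero, and with two testers
g(T1) = −g(T2) — hold exactly on every input. Standard errors use the
combined-ANOVA error mean square: SE(g_L) = √(MSE/ret),
SE(g_T) = √(MSE/rel), SE(s) = √(MSE/re); two-sided t tests on the
error df. With zero error df the effects are returned and inference is
withheld.

## Variance components, heritability, repeatability

Components are estimated by equating observed to expected mean squares
(method of moments), which is exact for balanced data and fully
reproducible; an REML backend could sit behind the same contract but is
not provided. The chain for the balanced design with centered effects:

    σ²_sca,e   = (MS_lte − MS_err) / r
    σ²_le      = (MS_le − MS_lte) / (r·t)
    σ²_te      = (MS_te − MS_lte) / (r·l)
    σ²_sca     = (MS_lt − MS_lte) / (r·e)
    σ²_gca,L   = (MS_l  − MS_le)  / (r·e·t)
    σ²_gca,T   = (MS_t  − MS_te)  / (r·e·l)

Negative estimates are truncated to zero and flagged. Both parents are
inbred lines, so by default F = 1 and

    σ²_A = [4/(1+F)] (σ²_gca,L + σ²_gca,T) = 2 (σ²_gca,L + σ²_gca,T)
    σ²_D = [4/(1+F)²] σ²_sca = σ²_sca

`f_coefficient` is exposed because this conversion is the single most
consequential convention in the analysis. Entry-mean narrow-sense
heritability is σ²_A / (σ²_A + σ²_D + σ²_GE/e + σ²_err/(re)) with
σ²_GE the additive- and dominance-by-environment components on the same
scale; repeatability is σ²_h / (σ²_h + σ²_h×e/e + σ²_err/(re)) with
σ²_h = (MS_hybrid − MS_hybrid×env)/(re). Both are clamped to [0, 1].

Note one finite-sample subtlety: the synthetic generator draws every
interaction effect exactly centered over each margin, so G×E cancels
from across-environment entry means and the moment estimator of σ²_h
over-corrects by σ²_h×e/e; the repeatability test derives its plug-in
expectation accordingly.

## Heterosis and heterotic grouping

Standard heterosis is H = 100 %(F₁ − CK)/CK where CK is the mean of
the hybrid between the two testers; infestation yield loss is
100 (y_non − y_inf)/y_non with negative losses flagged as gains.

Two classifiers assign lines to the groups the testers represent (the
mapping is a fixed constant: evidence with T1 ⇒ HGB, evidence with
T2 ⇒ HGA — a line that nicks with a tester belongs to the opposite
group):

- **SCA + yield**: SCA with one tester above `sca_threshold`
  (default 100 kg/ha, a yield-specific convention), negative SCA with
  the other, and testcross mean yield ≥ CK − LSD. The LSD is
  t(α/2, df_err)·√(2·MSE/(re)) because the underlying criterion is
  stated only as "not significantly different"; α and the gate are
  parameters. Lines failing any leg stay unassigned.
- **HSGCA**: positive HSGCA with T1 ⇒ HGB, positive with T2 ⇒ HGA;
  when both testers give the same sign, the tester with the smaller
  value decides (`tie_rule="min_value"`, reading "largest negative" as
  most negative; `"max_value"` gives the closest-to-zero reading). A
  configurable dead zone (default 0) can leave near-zero lines
  unclassified.

Consensus over conditions is unanimous agreement of the non-unassigned
calls; disagreement is reported as `inconsistent`.

## Marker diversity

Genotypes are biallelic dosages (0/1/2, NaN missing). QC drops markers
with missing fraction > 0.10, major-allele frequency > 0.95 (the filter
is deliberately on p_major, not minor-allele frequency), or observed
heterozygosity > 0.20; criteria are conjunctive, so filtering is
order-independent. Per-marker statistics over non-missing calls:
gene diversity 1 − p² − q², PIC = 1 − (p² + q²) − 2p²q², observed
heterozygosity, call rate; chromosome and global summaries are
unweighted marker means.

Distances are pairwise-complete. Jaccard expands each call into two
allele-presence bits (0→{A}, 1→{A,B}, 2→{B}) because Jaccard is
undefined on raw dosages; a shared-genotype variant sits behind a flag.
IBS distance is 1 − shared alleles/(2 × co-called), shared alleles per
marker = 2 − |dosage difference|. Ward clustering applies scipy's
Lance–Williams Ward update to the supplied dissimilarities (the
ward.D2 convention — named in output metadata because the ward.D /
ward.D2 ambiguity changes trees); merge heights are non-decreasing and
the dendrogram exports as Newick. Silhouette selection cuts the Ward
tree at k = 2…10 (k ≥ n skipped), ties to the smallest k. PCA
mean-imputes missing calls per marker, column-centers (no unit-variance
scaling by default; a flag exists because either convention is common),
and reports percent variance per axis from the singular values, summing
to 100.

Admixture-style population-structure estimation is out of scope; the
60 % membership convention for calling a line admixed applies only if
an externally produced Q-matrix is supplied.

## The synthetic generators

`simulate_trial` emulates the study conditions: 24 lines × 2 testers
plus 4 check-role hybrids (the tester cross and tolerant / susceptible
/ resistant checks) in a 13 × 4 lattice, r = 2, with 4 infested and 6
non-infested environments. Effect vectors are drawn Gaussian and then
exactly centered within each factor and margin, so estimator centering
identities are recoverable exactly in the noise-free limit and the
truth tables (every drawn effect, labelled) audit the pipeline end to
end. Yield variance components default to a realistic non-infested
savanna testcross scale (plot error SD ≈ 1,000 kg/ha, line-GCA SD ≈
560 kg/ha, grand mean 5,300 kg/ha); the lattice randomization is a
simple resolvable shuffle — the ANOVA only needs block labels.

Under infestation each plot receives a damage score (latent normal
around an entry propensity tied to −GCA, rounded and clamped to 1–9),
an emerged-parasite count (negative binomial, log-scale susceptibility
tied to −GCA; the distributional form is this package's stand-in, as
no field convention fixes it), and a yield multiplier 1 − loss(damage)
where loss is a logistic in the damage score calibrated through two
anchors: the susceptible check loses ≈80 % at score 8 and the tester
cross ≈31 % at score 4. Because the two conditions draw independent
environment effects, realized cross-condition loss percentages scatter
around those anchors. What the trial generator does **not** emulate:
spatial field trend, paired infested/non-infested strips sharing
environment effects, trait–trait genetic correlations, or
genotype–marker coupling (the trial and panel generators are
independent data streams). Passing tests therefore demonstrate
estimator correctness under the assumed model, not robustness to field
artefacts outside it.

`simulate_genotypes` draws a two-ancestral-population inbred panel:
ancestral frequencies Uniform(0.05, 0.95), population frequencies from
a Balding–Nichols-style Beta perturbation at the configured divergence
(default 0.25), homozygous draws, then residual heterozygous calls
(4 %) and sparse missing data. A designed number of markers violates
exactly one QC criterion each — the defaults scale 400 missing-fail /
600 frequency-fail / 252 heterozygosity-fail out of 3,305, leaving
2,053 clean — and clean markers are constructed (by capping injections
and nudging near-fixed frequencies) never to trip a filter by chance,
so QC retention is exact by construction. One integer seed drives
named, independently reproducible substreams (layout / noise /
parasite / genotypes).

## Numerical and design choices

- Missing plot values are NaN, never zero; estimators skip them and
  report effective n. Unbalanced cores get a least-squares fit on
  available data with the balance flag cleared.
- Damage scores and counts are analyzed untransformed by default; a
  log(x+1) transform for counts is available upstream of the ANOVA.
- Rank decisions in the sequential ANOVA use an SVD with tolerance
  s₁·max(n,p)·ε, matching standard matrix-rank practice.
- Problem sizes in the test and acceptance runs: property checks on
  l ≤ 6, e ≤ 3 balanced trials; parameter recovery on 200 replicates at
  l = 20, t = 2, e = 4, r = 2 (chosen so the line-GCA and SCA moment
  estimators resolve a 10 % bias bound; the tester-GCA mean square has
  a single df at t = 2, so its replicate mean is reported but not
  bounded); the marker chain on the full 26 × 3,305 panel.

## Known limitations

- The intrablock ANOVA does not recover interblock information; with
  very few entries per replicate the sequential block term can absorb
  treatment df.
- Method-of-moments components are exact only for balanced data;
  unbalanced trials get the same formulas applied to least-squares mean
  squares, with no REML refinement.
- Effects are raw-mean based; no BLUP/stage-wise analysis, no spatial
  modelling, no multi-trait models, no mid-parent heterosis (parents
  per se are not evaluated in a testcross trial).
- Genotype input is the dosage CSV/TSV with a marker-map sidecar, or a
  biallelic-SNP VCF (multiallelic sites rejected with a count).
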