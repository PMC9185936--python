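"""Synthetic trial phenotypes and SNP panels with known truth.

The trial generator emulates a two-tester factorial testcross trial laid
out as a resolvable incomplete-block (alpha-lattice) design over
multiple environments per research condition, with additive (line and
tester GCA), non-additive (SCA), genotype x environment, replicate,
block and residual plot effects. Under artificial infestation it
additionally generates per-plot host-damage scores (discretized latent
normal on the 1-9 scale), overdispersed emerged-parasite counts
(negative binomial with line-level susceptibility tied to the negative
of the line's yield GCA), and multiplies plot yield by a damage-driven
loss fraction calibrated through a logistic link.

The genotype generator draws a two-ancestral-population inbred panel:
ancestral allele frequencies are uniform, population frequencies come
from a Balding-Nichols-style Beta perturbation at the configured
divergence, genotypes are drawn homozygous and then residual
heterozygous calls and missing data are injected. A configured number
of markers is constructed to fail exactly one QC criterion each, so QC
filters can be audited against construction.

Every random effect drawn is recorded in the returned truth tables, and
all randomness flows from one integer seed through named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lxt.trial_io import Condition, EntryRole, testcross_name

CHECK_TOLERANT = "CHK_TOLERANT"
CHECK_SUSCEPTIBLE = "CHK_SUSCEPTIBLE"
CHECK_RESISTANT = "CHK_RESISTANT"
TESTER_CROSS = "T1xT2"


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, independently reproducible child stream of one integer seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class TraitSpec:
    """Per-trait grand means (by condition) and variance components."""

    mu: dict[str, float]
    sigma2_gca_line: float
    sigma2_gca_tester: float
    sigma2_sca: float
    sigma2_env: float
    sigma2_rep: float
    sigma2_block: float
    sigma2_line_env: float
    sigma2_tester_env: float
    sigma2_sca_env: float
    sigma2_error: float
    bounds: tuple[float | None, float | None] = (None, None)


def _default_traits() -> dict[str, TraitSpec]:
    # Yield variance components sized like a savanna testcross trial on
    # the non-infested (potential) scale; under infestation the damage ->
    # loss link shrinks the realized genetic variance organically.
    return {
        "yield": TraitSpec(
            mu={"infested": 5300.0, "non_infested": 5300.0},
            sigma2_gca_line=310_000.0,
            sigma2_gca_tester=90_000.0,
            sigma2_sca=130_000.0,
            sigma2_env=2_000_000.0,
            sigma2_rep=300_000.0,
            sigma2_block=170_000.0,
            sigma2_line_env=140_000.0,
            sigma2_tester_env=45_000.0,
            sigma2_sca_env=125_000.0,
            sigma2_error=1_000_000.0,
            bounds=(0.0, None),
        ),
        "days_to_anthesis": TraitSpec(
            mu={"infested": 58.0, "non_infested": 56.0},
            sigma2_gca_line=0.8,
            sigma2_gca_tester=0.4,
            sigma2_sca=0.1,
            sigma2_env=4.0,
            sigma2_rep=0.3,
            sigma2_block=0.2,
            sigma2_line_env=0.1,
            sigma2_tester_env=0.1,
            sigma2_sca_env=0.1,
            sigma2_error=2.0,
            bounds=(30.0, None),
        ),
        "ear_aspect": TraitSpec(
            mu={"infested": 3.2, "non_infested": 2.8},
            sigma2_gca_line=0.02,
            sigma2_gca_tester=0.01,
            sigma2_sca=0.01,
            sigma2_env=0.05,
            sigma2_rep=0.01,
            sigma2_block=0.01,
            sigma2_line_env=0.01,
            sigma2_tester_env=0.005,
            sigma2_sca_env=0.01,
            sigma2_error=0.1,
            bounds=(1.0, 5.0),
        ),
    }


@dataclass
class TrialSimConfig:
    """Study conditions for the trial generator.

    Defaults mirror a 24-line x 2-tester factorial with 4 check-role
    hybrids (the tester-cross plus tolerant, susceptible and commercial
    resistant checks) in a 13 x 4 alpha-lattice with 2 replications;
    4 infested and 6 non-infested environments.
    """

    n_lines: int = 24
    n_testers: int = 2
    environments: dict[str, int] = field(
        default_factory=lambda: {"infested": 4, "non_infested": 6}
    )
    replicates: int = 2
    lattice_blocks: int = 13
    lattice_block_size: int = 4
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    # infestation model
    damage_mu: float = 5.0  # mean testcross damage score on the 1-9 scale
    damage_sd: float = 0.9  # plot-level latent SD
    damage_gca_coef: float = 0.9  # damage shift per SD of (negative) yield GCA
    count_mu: float = 12.0  # mean emerged parasites per plot
    count_dispersion: float = 2.0  # negative-binomial size (smaller = more spread)
    count_gca_coef: float = 0.5  # log-scale shift per SD of (negative) yield GCA
    loss_max: float = 0.95  # asymptote of the damage -> yield-loss link
    # two calibration anchors (damage score, loss fraction): the
    # susceptible check loses ~80% at score 8, the tester-cross ~31% at 4
    loss_anchor_high: tuple[float, float] = (8.0, 0.80)
    loss_anchor_low: tuple[float, float] = (4.0, 0.31)
    check_yield_mu: dict[str, float] = field(
        default_factory=lambda: {
            TESTER_CROSS: 5000.0,
            CHECK_TOLERANT: 4800.0,
            CHECK_SUSCEPTIBLE: 4800.0,
            CHECK_RESISTANT: 5200.0,
        }
    )
    check_damage_mu: dict[str, float] = field(
        default_factory=lambda: {
            TESTER_CROSS: 4.0,
            CHECK_TOLERANT: 6.0,
            CHECK_SUSCEPTIBLE: 8.0,
            CHECK_RESISTANT: 4.7,
        }
    )
    seed: int = 0

    def line_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_lines)]

    def tester_names(self) -> list[str]:
        return [f"T{j + 1}" for j in range(self.n_testers)]

    def validate(self) -> None:
        n_entries = self.n_lines * self.n_testers + len(self.check_yield_mu)
        if n_entries > self.lattice_blocks * self.lattice_block_size:
            raise ValueError(
                f"{n_entries} entries exceed lattice capacity "
                f"{self.lattice_blocks} x {self.lattice_block_size}"
            )
        for name, spec in self.traits.items():
            for attr, val in vars(spec).items():
                if attr.startswith("sigma2") and val < 0:
                    raise ValueError(f"{name}.{attr} must be >= 0")


def _center(x: np.ndarray, axes=None) -> np.ndarray:
    """Project onto the interaction space: remove the mean over each axis."""
    if axes is None:
        axes = range(x.ndim)
    out = x.astype(float).copy()
    for ax in axes:
        out = out - out.mean(axis=ax, keepdims=True)
    return out


def loss_link(cfg: TrialSimConfig):
    """Logistic damage -> yield-loss function from the two anchors."""
    d1, p1 = cfg.loss_anchor_high
    d0, p0 = cfg.loss_anchor_low

    def logit(p):
        return np.log(p / (1 - p))

    b = (logit(p1 / cfg.loss_max) - logit(p0 / cfg.loss_max)) / (d1 - d0)
    mid = d1 - logit(p1 / cfg.loss_max) / b

    def loss(damage):
        return cfg.loss_max / (1.0 + np.exp(-b * (np.asarray(damage) - mid)))

    return loss


def _draw_effects(cfg: TrialSimConfig, trait: str, spec: TraitSpec, envs: list[str]):
    """Centered random-effect vectors for one trait over one condition."""
    l, t, e, r = cfg.n_lines, cfg.n_testers, len(envs), cfg.replicates
    rng = stream_rng(cfg.seed, f"trial/{trait}/{envs[0].split('-')[0]}")
    eff = {}
    eff["gca_line"] = _center(rng.normal(0, np.sqrt(spec.sigma2_gca_line), l))
    eff["gca_tester"] = _center(rng.normal(0, np.sqrt(spec.sigma2_gca_tester), t))
    eff["sca"] = _center(rng.normal(0, np.sqrt(spec.sigma2_sca), (l, t)))
    eff["env"] = rng.normal(0, np.sqrt(spec.sigma2_env), e)
    eff["rep"] = _center(rng.normal(0, np.sqrt(spec.sigma2_rep), (e, r)), axes=[1])
    eff["block"] = _center(
        rng.normal(0, np.sqrt(spec.sigma2_block), (e, r, cfg.lattice_blocks)),
        axes=[2],
    )
    eff["line_env"] = _center(rng.normal(0, np.sqrt(spec.sigma2_line_env), (l, e)))
    eff["tester_env"] = _center(
        rng.normal(0, np.sqrt(spec.sigma2_tester_env), (t, e))
    )
    eff["sca_env"] = _center(rng.normal(0, np.sqrt(spec.sigma2_sca_env), (l, t, e)))
    return eff


def simulate_trial(cfg: TrialSimConfig | None = None):
    """Generate one multi-environment trial plus complete truth tables.

    Returns ``(frame, truth)`` where *frame* is the tidy plot table and
    *truth* maps trait -> dict of the drawn effect tables (as labelled
    pandas objects) plus the damage/count/loss model pieces.
    """
    cfg = cfg or TrialSimConfig()
    cfg.validate()
    lines, testers = cfg.line_names(), cfg.tester_names()
    checks = list(cfg.check_yield_mu)
    entries = [testcross_name(li, te) for li in lines for te in testers] + checks
    loss = loss_link(cfg)

    yield_spec = cfg.traits["yield"]
    rows: list[dict] = []
    truth: dict = {}
    layout_rng = stream_rng(cfg.seed, "trial/layout")
    noise_rng = stream_rng(cfg.seed, "trial/noise")
    striga_rng = stream_rng(cfg.seed, "trial/striga")

    g_yield_sd = max(np.sqrt(yield_spec.sigma2_gca_line), 1e-12)

    for condition, n_env in cfg.environments.items():
        cond = Condition(condition).value
        envs = [f"{'INF' if cond == 'infested' else 'NON'}-E{k + 1}" for k in range(n_env)]
        per_trait_eff = {}
        for trait, spec in cfg.traits.items():
            per_trait_eff[trait] = _draw_effects(cfg, trait, spec, envs)
        g_line_yield = per_trait_eff["yield"]["gca_line"]
        g_std = g_line_yield / g_yield_sd

        # entry-level infestation propensities (testcrosses follow -GCA)
        damage_entry = {
            testcross_name(li, te): cfg.damage_mu - cfg.damage_gca_coef * g_std[i]
            for i, li in enumerate(lines)
            for te in testers
        }
        damage_entry.update(cfg.check_damage_mu)
        count_entry = {
            testcross_name(li, te): cfg.count_mu * np.exp(-cfg.count_gca_coef * g_std[i])
            for i, li in enumerate(lines)
            for te in testers
        }
        for chk, dmu in cfg.check_damage_mu.items():
            # checks: parasite pressure scales with their damage propensity
            count_entry[chk] = cfg.count_mu * dmu / cfg.damage_mu

        truth[cond] = {
            trait: {
                "gca_line": pd.Series(eff["gca_line"], index=lines),
                "gca_tester": pd.Series(eff["gca_tester"], index=testers),
                "sca": pd.DataFrame(eff["sca"], index=lines, columns=testers),
                "env": pd.Series(eff["env"], index=envs),
            }
            for trait, eff in per_trait_eff.items()
        }
        truth[cond]["damage_entry_mean"] = pd.Series(damage_entry)
        truth[cond]["count_entry_mean"] = pd.Series(count_entry)

        for ek, env in enumerate(envs):
            for rep in range(cfg.replicates):
                order = layout_rng.permutation(len(entries))
                for pos, entry_idx in enumerate(order):
                    entry = entries[entry_idx]
                    block = pos // cfg.lattice_block_size
                    is_check = entry in checks
                    row = {
                        "environment": env,
                        "condition": cond,
                        "replicate": rep + 1,
                        "block": f"B{block + 1:02d}",
                        "entry": entry,
                        "entry_role": (
                            EntryRole.TESTER_CROSS.value
                            if entry == TESTER_CROSS
                            else EntryRole.CHECK.value
                            if is_check
                            else EntryRole.TESTCROSS.value
                        ),
                        "line": None if is_check else entry.split("x")[0],
                        "tester": None if is_check else entry.split("x")[1],
                    }
                    if not is_check:
                        i = lines.index(row["line"])
                        j = testers.index(row["tester"])
                    for trait, spec in cfg.traits.items():
                        eff = per_trait_eff[trait]
                        base = (
                            eff["env"][ek]
                            + eff["rep"][ek, rep]
                            + eff["block"][ek, rep, block]
                        )
                        if is_check:
                            mu = (
                                cfg.check_yield_mu[entry]
                                if trait == "yield"
                                else spec.mu[cond]
                            )
                            value = mu + base
                        else:
                            value = (
                                spec.mu[cond]
                                + base
                                + eff["gca_line"][i]
                                + eff["gca_tester"][j]
                                + eff["sca"][i, j]
                                + eff["line_env"][i, ek]
                                + eff["tester_env"][j, ek]
                                + eff["sca_env"][i, j, ek]
                            )
                        if spec.sigma2_error > 0:
                            value += noise_rng.normal(0, np.sqrt(spec.sigma2_error))
                        row[trait] = value

                    if cond == Condition.INFESTED.value:
                        latent = damage_entry[entry]
                        if cfg.damage_sd > 0:
                            latent += striga_rng.normal(0, cfg.damage_sd)
                        damage = float(np.clip(np.round(latent), 1, 9))
                        row["striga_damage"] = damage
                        mean_count = count_entry[entry]
                        k = cfg.count_dispersion
                        row["striga_count"] = int(
                            striga_rng.negative_binomial(k, k / (k + mean_count))
                        )
                        row["yield"] = row["yield"] * (1.0 - float(loss(damage)))
                    for trait, spec in cfg.traits.items():
                        lo, hi = spec.bounds
                        if lo is not None:
                            row[trait] = max(row[trait], lo)
                        if hi is not None:
                            row[trait] = min(row[trait], hi)
                    rows.append(row)

    frame = pd.DataFrame(rows)
    truth["loss_link"] = loss
    return frame, truth


@dataclass
class GenoSimConfig:
    """Study conditions for the inbred SNP-panel generator.

    Defaults emulate a 26-sample, 3,305-marker targeted SNP panel on 10
    chromosomes from two ancestral populations, with ~4% residual
    heterozygosity, sparse missing data, and a designed number of
    markers failing exactly one QC criterion each (the remainder are
    constructed to pass all three filters).
    """

    n_samples: int = 26
    n_markers: int = 3305
    n_populations: int = 2
    divergence: float = 0.25  # Balding-Nichols F-like drift parameter
    residual_het_rate: float = 0.04
    missing_rate: float = 0.02
    # None = scale the flagship panel's designed failure counts
    # (400 / 600 / 252 out of 3,305, leaving 2,053 clean) to n_markers
    qc_fail_missing: int | None = None
    qc_fail_maf: int | None = None  # forced (near-)monomorphic
    qc_fail_het: int | None = None
    n_chromosomes: int = 10
    freq_range: tuple[float, float] = (0.05, 0.95)
    sample_names: list[str] | None = None
    seed: int = 0

    _FLAGSHIP = (400, 600, 252, 3305)

    def qc_counts(self) -> tuple[int, int, int]:
        miss, maf, het, total = self._FLAGSHIP
        scale = self.n_markers / total
        return (
            int(round(miss * scale)) if self.qc_fail_missing is None else self.qc_fail_missing,
            int(round(maf * scale)) if self.qc_fail_maf is None else self.qc_fail_maf,
            int(round(het * scale)) if self.qc_fail_het is None else self.qc_fail_het,
        )

    def validate(self) -> None:
        if sum(self.qc_counts()) > self.n_markers:
            raise ValueError("QC-violation counts exceed the marker count")
        for name in ("divergence", "residual_het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def simulate_genotypes(cfg: GenoSimConfig | None = None):
    """Generate an inbred two-population SNP panel plus truth labels.

    Returns ``(genotypes, truth)``; *truth* holds the population label
    per sample, the per-marker QC fate designed at construction, and the
    population allele frequencies.
    """
    from lxt.marker_diversity import GenotypeMatrix

    cfg = cfg or GenoSimConfig()
    cfg.validate()
    rng = stream_rng(cfg.seed, "genotypes")
    n, m = cfg.n_samples, cfg.n_markers
    samples = cfg.sample_names or [f"S{i + 1:02d}" for i in range(n)]
    if len(samples) != n:
        raise ValueError("sample_names length must equal n_samples")

    pops = np.array([i % cfg.n_populations for i in range(n)])
    p_anc = rng.uniform(*cfg.freq_range, size=m)
    f = cfg.divergence
    if f > 0:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_pop = rng.beta(a[None, :].repeat(cfg.n_populations, 0), b[None, :].repeat(cfg.n_populations, 0))
    else:
        p_pop = np.tile(p_anc, (cfg.n_populations, 1))

    # inbred homozygous draws from each sample's population frequency
    calls = 2.0 * (rng.random((n, m)) < p_pop[pops, :])

    n_fail_missing, n_fail_maf, n_fail_het = cfg.qc_counts()
    fate = np.full(m, "clean", dtype=object)
    cursor = 0
    idx_missing = np.arange(cursor, cursor + n_fail_missing); cursor += n_fail_missing
    idx_maf = np.arange(cursor, cursor + n_fail_maf); cursor += n_fail_maf
    idx_het = np.arange(cursor, cursor + n_fail_het); cursor += n_fail_het
    fate[idx_missing] = "fail_missing"
    fate[idx_maf] = "fail_maf"
    fate[idx_het] = "fail_het"
    # shuffle marker order so designed fates are spread over the genome
    perm = rng.permutation(m)
    fate = fate[perm]
    inv = np.empty(m, dtype=int)
    inv[perm] = np.arange(m)
    idx_missing, idx_maf, idx_het = inv[idx_missing], inv[idx_maf], inv[idx_het]
    clean = np.flatnonzero(fate == "clean")

    max_het_calls = int(np.floor(0.20 * n))  # keep clean markers under the filter
    max_missing_calls = int(np.floor(0.10 * n))

    # residual heterozygosity on clean + missing-fail markers, capped so a
    # clean marker never trips the 20% filter by chance
    het_targets = np.concatenate([clean, idx_missing])
    for jm in het_targets:
        n_het = min(rng.binomial(n, cfg.residual_het_rate), max_het_calls)
        if n_het:
            calls[rng.choice(n, n_het, replace=False), jm] = 1.0

    # sparse missing data on clean markers, capped under the 10% filter
    if cfg.missing_rate > 0:
        for jm in clean:
            n_miss = min(rng.binomial(n, cfg.missing_rate), max_missing_calls)
            if n_miss:
                calls[rng.choice(n, n_miss, replace=False), jm] = np.nan

    # clean markers must also pass the MAF filter: nudge near-fixed ones
    for jm in clean:
        col = calls[:, jm]
        called = ~np.isnan(col)
        p_alt = col[called].sum() / (2 * called.sum())
        p_major = max(p_alt, 1 - p_alt)
        while p_major > 0.95:
            homo_major = np.flatnonzero(called & (col == (2.0 if p_alt > 0.5 else 0.0)))
            col[rng.choice(homo_major)] = 2.0 - col[homo_major[0]]
            p_alt = col[called].sum() / (2 * called.sum())
            p_major = max(p_alt, 1 - p_alt)

    # designed violations
    for jm in idx_missing:  # > 10% missing
        k = max(max_missing_calls + 1, int(np.ceil(0.15 * n)))
        calls[rng.choice(n, k, replace=False), jm] = np.nan
    calls[:, idx_maf] = 0.0  # monomorphic: major allele frequency 1
    for jm in idx_het:  # > 20% heterozygous calls
        k = max(max_het_calls + 1, int(np.ceil(0.5 * n)))
        calls[rng.choice(n, k, replace=False), jm] = 1.0

    chrom = np.sort(rng.integers(1, cfg.n_chromosomes + 1, size=m))
    pos = np.zeros(m, dtype=int)
    for c in range(1, cfg.n_chromosomes + 1):
        on_c = np.flatnonzero(chrom == c)
        pos[on_c] = np.sort(rng.integers(1, 300_000_000, size=len(on_c)))
    marker_map = pd.DataFrame(
        {
            "marker": [f"M{j + 1:05d}" for j in range(m)],
            "chromosome": chrom.astype(str),
            "position": pos,
        }
    )

    genotypes = GenotypeMatrix(samples=samples, calls=calls, marker_map=marker_map)
    truth = {
        "population": pd.Series(pops, index=samples, name="population"),
        "marker_fate": pd.Series(fate, index=marker_map["marker"], name="fate"),
        "pop_frequencies": p_pop,
    }
    return genotypes, truth
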