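"""Full-pipeline assembly: ANOVA -> effects -> heterosis -> grouping -> markers.

Stages are independent where the inputs allow: a trial table drives the
combining-ability, heterosis and grouping stages; a genotype matrix
drives the marker stages. A stage whose input is absent is skipped with
an explicit status, and a stage failure does not stop the remaining
independent stages. Every output CSV carries a metadata comment line
(tool version, seed, config hash) so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

import lxt
from lxt import combining_ability as ca
from lxt import heterosis_grouping as hg
from lxt import marker_diversity as md
from lxt import trial_io
from lxt.synthetic_data import TESTER_CROSS


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    trial_path: str | None = None
    genotype_path: str | None = None
    marker_map_path: str | None = None
    out_dir: str = "lxt_out"
    traits: list[str] = field(default_factory=lambda: ["yield"])
    conditions: list[str] = field(
        default_factory=lambda: ["infested", "non_infested"]
    )
    grouping_methods: list[str] = field(
        default_factory=lambda: ["sca_yield", "hsgca"]
    )
    ck_entry: str = TESTER_CROSS
    sca_threshold: float = 100.0
    alpha: float = 0.05
    tie_rule: str = "min_value"
    dead_zone: float = 0.0
    f_coefficient: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sca_threshold < 0 or self.dead_zone < 0:
            raise ValueError("thresholds must be non-negative")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(frame: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False):
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# lxt {lxt.__version__} seed={cfg.seed} config={cfg.config_hash()}\n"
        )
        frame.to_csv(fh, index=index)


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Run every stage the inputs allow; returns a per-stage status report."""
    out = Path(cfg.out_dir)
    status: dict[str, str] = {}
    manifest = {
        "version": lxt.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
    }

    frame = None
    if cfg.trial_path:
        frame = trial_io.read_trial_csv(cfg.trial_path)

    if frame is None:
        for stage in ("anova", "effects", "heterosis", "grouping"):
            status[stage] = "skipped: no trial data"
    else:
        assignments: list[hg.GroupAssignment] = []
        for trait in cfg.traits:
            for condition in cfg.conditions:
                tag = f"{trait}_{condition}"
                try:
                    an = ca.anova_line_by_tester(frame, trait, condition)
                    _write(an.to_frame(), out / f"anova_{tag}.csv", cfg, index=True)
                    vc = ca.estimate_variance_components(an, cfg.f_coefficient)
                    _write(
                        pd.DataFrame([{k: v for k, v in vars(vc).items() if k != "truncated"}]),
                        out / f"variance_components_{tag}.csv",
                        cfg,
                    )
                    status[f"anova:{tag}"] = "ok"
                except Exception as exc:  # keep independent stages running
                    status[f"anova:{tag}"] = f"failed: {exc}"
                    continue
                try:
                    res = ca.estimate_gca_sca(frame, trait, condition, anova=an)
                    _write(res.effects_frame(), out / f"effects_{tag}.csv", cfg)
                    status[f"effects:{tag}"] = "ok"
                except Exception as exc:
                    status[f"effects:{tag}"] = f"failed: {exc}"
                    continue

                if trait != "yield":
                    continue
                try:
                    means = trial_io.cell_means(frame, trait, condition)
                    means = means.set_index("entry")["mean"]
                    if cfg.ck_entry not in means.index:
                        raise KeyError(f"check entry {cfg.ck_entry!r} not found")
                    ck_mean = float(means[cfg.ck_entry])
                    het = hg.heterosis_table(
                        means.drop(cfg.ck_entry), ck_mean, trait, condition
                    )
                    _write(het, out / f"heterosis_{tag}.csv", cfg)
                    status[f"heterosis:{tag}"] = "ok"
                except Exception as exc:
                    status[f"heterosis:{tag}"] = f"failed: {exc}"
                    ck_mean = None
                try:
                    tc_means = (
                        frame[
                            (frame["condition"] == condition)
                            & (frame["entry_role"] == "testcross")
                        ]
                        .groupby(["line", "tester"])[trait]
                        .mean()
                        .unstack("tester")
                    )
                    if "sca_yield" in cfg.grouping_methods and ck_mean is not None:
                        lsd = hg.lsd_yield(an, cfg.alpha)
                        assignments += hg.assign_groups_sca_yield(
                            res, tc_means, ck_mean, lsd, cfg.sca_threshold
                        )
                    if "hsgca" in cfg.grouping_methods:
                        assignments += hg.assign_groups_hsgca(
                            hg.hsgca_effects(res),
                            tie_rule=cfg.tie_rule,
                            condition=condition,
                            dead_zone=cfg.dead_zone,
                        )
                    status[f"grouping:{tag}"] = "ok"
                except Exception as exc:
                    status[f"grouping:{tag}"] = f"failed: {exc}"
        if assignments:
            table = pd.DataFrame(
                [
                    {
                        "line": a.line,
                        "method": a.method,
                        "condition": a.condition,
                        "group": a.group.value,
                    }
                    for a in assignments
                ]
            )
            _write(table, out / "grouping_assignments.csv", cfg)
            _write(hg.consensus_groups(assignments), out / "grouping_consensus.csv", cfg)

    if not cfg.genotype_path:
        status["markers"] = "skipped: no genotypes"
    else:
        try:
            g = md.GenotypeMatrix.read_csv(cfg.genotype_path, cfg.marker_map_path)
            filtered, qc = md.filter_markers(g)
            _write(qc, out / "marker_qc.csv", cfg)
            stats = md.marker_summary(filtered)
            _write(stats, out / "marker_stats.csv", cfg)
            _write(
                stats.attrs["by_chromosome"].reset_index(),
                out / "marker_stats_by_chromosome.csv",
                cfg,
            )
            for metric, fn in (("jaccard", md.jaccard_distance), ("ibs", md.ibs_distance)):
                dist = fn(filtered)
                _write(dist.to_frame(), out / f"distance_{metric}.csv", cfg, index=True)
                if metric == "jaccard":
                    clust = md.ward_cluster(dist)
                    (out / "dendrogram.nwk").write_text(clust.newick())
                    best_k, scores = md.silhouette_k(dist)
                    _write(scores, out / "silhouette.csv", cfg)
                    _write(
                        clust.cut(best_k).rename_axis("sample").reset_index(),
                        out / f"clusters_k{best_k}.csv",
                        cfg,
                    )
            scores_pca, pct = md.pca_genotypes(filtered)
            scores_pca = scores_pca.copy()
            _write(scores_pca, out / "pca_scores.csv", cfg, index=True)
            _write(
                pd.DataFrame(
                    {"axis": [f"PC{i+1}" for i in range(len(pct))], "percent_variance": pct}
                ),
                out / "pca_percent_variance.csv",
                cfg,
            )
            status["markers"] = "ok"
        except Exception as exc:
            status["markers"] = f"failed: {exc}"

    manifest["status"] = status
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return status
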