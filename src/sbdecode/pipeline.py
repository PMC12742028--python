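"""End-to-end orchestration: simulate → features → decode → statistics.

A single :class:`RunConfig` drives the full analysis; one global seed is
expanded into per-stage child seeds through ``numpy.random.SeedSequence``
(stage order is fixed: cohort, then one child per decoding task in listed
order), so any stage can be re-run in isolation and identical configs
reproduce identical result JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexity, decoding, simulate, spectral, stats
from .protocol import REST, SB_MINUS, SB_PLUS, SessionProtocol, default_protocol

__all__ = ["RunConfig", "run_all", "report", "cohort_feature_table", "config_from_yaml"]

_PRESETS = {
    "null": simulate.EffectSpec.null,
    "study_like": simulate.EffectSpec.study_like,
    "strong_beta": simulate.EffectSpec.strong_beta,
}

CONTRASTS = {
    "sbm-rest": (SB_MINUS, REST),
    "sbm-sbp": (SB_MINUS, SB_PLUS),
}

# a priori direction of the univariate hypothesis per feature kind:
# oscillatory power drops and complexity rises in self-boundary dissolution
_DIRECTIONS = {"lzc": stats.HIGH_IS_POSITIVE}


@dataclass
class RunConfig:
    n_participants: int = 10
    effects: str = "null"  # preset name
    between_participant_sd: float = 0.0
    features: tuple[str, ...] = ("lzc",)  # "lzc", "band:<name>", "aperiodic"
    contrasts: tuple[str, ...] = ("sbm-rest",)
    classifiers: tuple[str, ...] = ("lr",)
    modes: tuple[str, ...] = ("within",)
    seed: int = 0
    region_count: int = 62
    protocol: SessionProtocol | None = None
    out_dir: str | None = None
    smote_eval: bool = True

    def __post_init__(self) -> None:
        for f in self.features:
            if f not in ("lzc", "aperiodic") and not f.startswith("band:"):
                raise ValueError(f"unknown feature set {f!r}")
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}")
        for m in self.modes:
            if m not in ("within", "across"):
                raise ValueError(f"unknown mode {m!r}")
        for clf in self.classifiers:
            if clf not in decoding.DEFAULT_GRIDS:
                raise ValueError(f"unknown classifier {clf!r}")
        if self.effects not in _PRESETS:
            raise ValueError(f"unknown effects preset {self.effects!r}")


def config_from_yaml(path: str | Path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "protocol" in raw:
        layout = tuple((str(s), int(d)) for s, d in raw.pop("protocol"))
        raw["protocol"] = SessionProtocol(
            block_layout=layout, sampling_rate=float(raw.pop("sampling_rate", 300.0))
        )
    for key in ("features", "contrasts", "classifiers", "modes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _feature_prefix(feature: str) -> str:
    return feature.split(":", 1)[1] if feature.startswith("band:") else feature


def cohort_feature_table(
    sessions: list[simulate.ParcelTimeSeries], features: tuple[str, ...]
) -> dict[str, pd.DataFrame]:
    """One cohort-level table per feature kind ('lzc' and/or 'spectral')."""
    tables: dict[str, pd.DataFrame] = {}
    if "lzc" in features:
        lzc = complexity.LZComplexityFeaturizer()
        tables["lzc"] = pd.concat(
            [lzc.transform(ts) for ts in sessions], ignore_index=True
        )
    spectral_feats = [f for f in features if f != "lzc"]
    if spectral_feats:
        names = {_feature_prefix(f) for f in spectral_feats if f != "aperiodic"}
        bands = tuple(b for b in spectral.DEFAULT_BANDS if b.name in names)
        missing = names - {b.name for b in bands}
        if missing:
            raise ValueError(f"unknown band names {sorted(missing)}")
        feat = spectral.SpectralFeaturizer(bands=bands)
        tables["spectral"] = pd.concat(
            [feat.transform(ts) for ts in sessions], ignore_index=True
        )
    return tables


def _univariate_task(
    table: pd.DataFrame, prefix: str, contrast: tuple[str, str]
) -> dict:
    """Best-region grand-mean threshold accuracy, pooled across participants."""
    from .parcellation import feature_columns

    cols = feature_columns(table, prefix)
    direction = _DIRECTIONS.get(prefix, stats.LOW_IS_POSITIVE)
    pos = table[table["state"] == contrast[0]]
    oth = table[table["state"] == contrast[1]]
    accs = {
        c: stats.univariate_threshold_accuracy(
            pos[c].to_numpy(), oth[c].to_numpy(), direction
        )
        for c in cols
    }
    best = max(accs, key=lambda c: accs[c])
    n1, n2 = len(pos), len(oth)
    n = max(1, int(round(4.0 / (1.0 / n1 + 1.0 / n2))))
    k = min(n, max(0, int(round(accs[best] * n))))
    # the best region is selected post hoc, so its binomial p is
    # Bonferroni-corrected for the number of regions searched
    p_best = min(1.0, stats.binomial_vs_chance(k, n) * len(cols))
    d = {c: stats.cohens_d(pos[c].to_numpy(), oth[c].to_numpy()) for c in cols}
    return {
        "best_region": best,
        "accuracy": accs[best],
        "p": p_best,
        "cohens_d_range": [min(d.values()), max(d.values())],
        "direction": direction,
    }


def run_all(config: RunConfig) -> dict:
    """Run the configured analysis end to end; returns the results bundle."""
    seeds = np.random.SeedSequence(config.seed)
    cohort_seed = int(seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
    protocol = config.protocol or default_protocol()
    effects = _PRESETS[config.effects](region_count=config.region_count)
    sessions = simulate.generate_cohort(
        config.n_participants,
        effects,
        between_participant_sd=config.between_participant_sd,
        seed=cohort_seed,
        protocol=protocol,
    )
    tables = cohort_feature_table(sessions, config.features)

    results: list[dict] = []
    importance: dict[str, list[dict]] = {}
    test_rows: list[dict] = []
    task_idx = 0
    for feature in config.features:
        prefix = _feature_prefix(feature)
        table = tables["lzc" if feature == "lzc" else "spectral"]
        for contrast_name in config.contrasts:
            contrast = CONTRASTS[contrast_name]
            uni = _univariate_task(table, prefix, contrast)
            test_rows.append(
                {
                    "test_id": f"univariate|{feature}|{contrast_name}",
                    "family": "univariate",
                    "p_raw": uni["p"],
                }
            )
            results.append(
                {"task": "univariate", "feature": feature,
                 "contrast": contrast_name, **uni}
            )
            for mode in config.modes:
                for family in config.classifiers:
                    task_idx += 1
                    task_seed = int((config.seed * 10007 + task_idx) % (2**31))
                    entry = {
                        "task": "decode", "feature": feature,
                        "contrast": contrast_name, "mode": mode,
                        "classifier": family,
                    }
                    if mode == "within":
                        per_part: dict[str, decoding.DecodeResult] = {}
                        coef_sum = None
                        contrast_rows = table[table["state"].isin(contrast)]
                        for pid, sub in contrast_rows.groupby("participant", sort=True):
                            sub = sub.sort_values("epoch_idx").reset_index(drop=True)
                            split = decoding.within_participant_split(sub)
                            res = decoding.fit_and_evaluate(
                                split, sub, contrast, family=family,
                                feature_prefix=prefix, seed=task_seed,
                                smote_eval=config.smote_eval,
                            )
                            per_part[pid] = res
                            if res.coefficients is not None:
                                coef_sum = (
                                    res.coefficients
                                    if coef_sum is None
                                    else coef_sum + res.coefficients
                                )
                        summary = stats.participant_summary(per_part)
                        entry.update(
                            accuracy=summary.mean_accuracy,
                            ci95=list(summary.ci95),
                            fisher_chi2=summary.fisher_chi2,
                            p=summary.fisher_p,
                            per_participant_accuracy={
                                pid: r.accuracy for pid, r in per_part.items()
                            },
                        )
                        if family == "lr" and coef_sum is not None:
                            mean_coef = coef_sum / len(per_part)
                            order = mean_coef.abs().sort_values(
                                ascending=False, kind="stable"
                            ).index
                            importance[f"{feature}|{contrast_name}|within"] = [
                                {"feature": c, "coefficient": float(mean_coef[c])}
                                for c in order
                            ]
                    else:
                        split = decoding.across_participant_split(
                            table, seed=task_seed
                        )
                        res = decoding.fit_and_evaluate(
                            split, table, contrast, family=family,
                            feature_prefix=prefix, seed=task_seed,
                            smote_eval=config.smote_eval,
                        )
                        entry.update(
                            accuracy=res.accuracy,
                            p=stats.binomial_vs_chance(res.k_correct, res.n_eval),
                            n_eval=res.n_eval,
                        )
                        if res.coefficients is not None:
                            ranked = decoding.feature_importance(res)
                            importance[f"{feature}|{contrast_name}|across"] = (
                                ranked.to_dict(orient="records")
                            )
                    test_rows.append(
                        {
                            "test_id": f"decode|{feature}|{contrast_name}|{mode}|{family}",
                            "family": "multivariate",
                            "p_raw": entry["p"],
                        }
                    )
                    results.append(entry)

    stats_report = stats.build_stats_report(pd.DataFrame(test_rows))
    bundle = {
        "config": _config_dict(config),
        "results": results,
        "importance": importance,
        "stats": stats_report.tests.to_dict(orient="records"),
    }
    if config.out_dir is not None:
        _write_bundle(bundle, stats_report, Path(config.out_dir))
    return bundle


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d.pop("out_dir", None)  # execution detail; keeps summaries comparable
    if config.protocol is not None:
        d["protocol"] = {
            "block_layout": [list(seg) for seg in config.protocol.block_layout],
            "sampling_rate": config.protocol.sampling_rate,
        }
    return d


def _write_bundle(bundle: dict, stats_report: stats.StatsReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    summary = out / "summary.json"
    summary.write_text(json.dumps(bundle, indent=1, sort_keys=True, default=str))
    files["summary.json"] = summary
    tests_tsv = out / "tests.tsv"
    stats_report.tests.to_csv(tests_tsv, sep="\t", index=False)
    files["tests.tsv"] = tests_tsv
    report_md = out / "report.md"
    report_md.write_text(report(bundle))
    files["report.md"] = report_md
    manifest = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def report(bundle: dict) -> str:
    """Human-readable markdown summary: one row per task, then importance."""
    lines = ["# Decoding results", ""]
    lines.append("| task | feature | contrast | mode | classifier | accuracy | p |")
    lines.append("|---|---|---|---|---|---|---|")
    for entry in bundle["results"]:
        if entry["task"] != "decode":
            continue
        lines.append(
            "| decode | {feature} | {contrast} | {mode} | {classifier} "
            "| {accuracy:.3f} | {p:.3g} |".format(**entry)
        )
    uni = [e for e in bundle["results"] if e["task"] == "univariate"]
    if uni:
        lines += ["", "## Univariate benchmark (best region, grand-mean threshold)",
                  "", "| feature | contrast | region | accuracy | p |", "|---|---|---|---|---|"]
        for e in uni:
            lines.append(
                "| {feature} | {contrast} | {best_region} | {accuracy:.3f} "
                "| {p:.3g} |".format(**e)
            )
    for key, ranked in bundle.get("importance", {}).items():
        lines += ["", f"## Feature importance — {key} (top 10 |coefficient|)", ""]
        lines.append("| rank | region | coefficient |")
        lines.append("|---|---|---|")
        for rank, row in enumerate(ranked[:10], start=1):
            lines.append(f"| {rank} | {row['feature']} | {row['coefficient']:+.4f} |")
    incomplete = [e for e in bundle["results"] if e.get("incomplete")]
    if incomplete:
        lines += ["", f"WARNING: {len(incomplete)} incomplete tasks."]
    return "\n".join(lines) + "\n"
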