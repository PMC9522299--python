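"""End-to-end orchestration: scan, ICC summaries, benchmark, report tables.

``run_pipeline`` executes, for each configured session subset (for example
``all`` sites and the Siemens-only subset):

1. the per-phenotype site-effect battery with class-wise FDR;
2. per-phenotype consistency ICCs, pairwise-session ICCs and per-class
   mean/SD summaries;
3. optionally, benchmarking of each phenotype's ICC against subsample
   resampling of a reference test-retest cohort.

Outputs are tidy TSVs (one per-phenotype table and one per-class table per
subset) plus a JSON manifest recording seeds, subset definitions and row
counts, so that identical config + seed reproduce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import empirical_two_sided_p, resample_reference_iccs
from .errors import ConfigurationError
from .reliability import class_icc_summary, icc_scan, pairwise_icc
from .site_effects import site_effect_scan
from .tables import IDPTable, read_idp_table

__all__ = ["RunConfig", "ReliabilityReport", "run_pipeline", "class_proportions"]


@dataclass
class RunConfig:
    """Configuration of a full reliability run.

    ``subsets`` maps a subset name to either the string ``"all"``, a
    manufacturer name (``"SIEMENS"``/``"GE"``), or an explicit list of
    session labels.
    """

    study_path: str
    sessions_path: str | None = None
    class_map_path: str | None = None
    reference_path: str | None = None
    subsets: dict = field(default_factory=lambda: {"all": "all"})
    q: float = 0.05
    gg_alpha: float = 0.05
    icc_method: str = "anova"
    pairwise: bool = True
    subset_size: int = 8
    n_resamples: int = 1000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReliabilityReport:
    """Result tables of one pipeline run, keyed by subset name."""

    per_idp: dict
    per_class: pd.DataFrame
    manifest: dict

    def frame(self, subset: str) -> pd.DataFrame:
        return self.per_idp[subset]


def _resolve_subset(table: IDPTable, spec) -> list[str]:
    if isinstance(spec, str):
        if spec.lower() == "all":
            return table.session_labels
        return table.subset_sessions(spec)
    labels = sorted(spec)
    missing = set(labels) - set(table.session_labels)
    if missing:
        raise ConfigurationError(f"unknown session labels: {sorted(missing)}")
    return labels


def run_pipeline(config: RunConfig, table: IDPTable | None = None,
                 reference: IDPTable | None = None) -> ReliabilityReport:
    """Run the full battery per configured subset; write outputs if asked.

    ``table``/``reference`` may be passed in directly (already-built
    objects); otherwise they are read from the configured paths.
    """
    if table is None:
        table = read_idp_table(
            config.study_path,
            sessions_path=config.sessions_path,
            class_map_path=config.class_map_path,
        )
    if reference is None and config.reference_path:
        reference = read_idp_table(config.reference_path)

    seed_root = np.random.SeedSequence(config.seed)

    per_idp: dict = {}
    class_frames = []
    manifest = {
        "idprel_version": __version__,
        "seed": config.seed,
        "q": config.q,
        "icc_method": config.icc_method,
        "subsets": {},
        "n_idps": len(table.idp_names),
    }

    for subset_name in sorted(config.subsets):
        sessions = _resolve_subset(table, config.subsets[subset_name])
        if len(sessions) < 2:
            raise ConfigurationError(
                f"subset {subset_name!r} resolves to < 2 sessions: {sessions}"
            )
        scan = site_effect_scan(
            table, sessions=sessions, q=config.q, gg_alpha=config.gg_alpha
        )
        iccs = icc_scan(table, sessions=sessions, method=config.icc_method)
        merged = scan.merge(
            iccs[
                ["idp_name", "icc", "sigma2_subject", "sigma2_error",
                 "negative", "degenerate"]
            ],
            on="idp_name",
            how="left",
        )

        if config.pairwise:
            pair_cols: dict = {}
            for idp in table.idp_names:
                for pair, res, _reason in pairwise_icc(
                    table, idp, sessions=sessions, method=config.icc_method
                ):
                    col = f"icc_pair_{pair[0]}_{pair[1]}"
                    pair_cols.setdefault(col, {})[idp] = (
                        res.icc if res is not None else np.nan
                    )
            for col in sorted(pair_cols):
                merged[col] = merged["idp_name"].map(pair_cols[col])

        if reference is not None:
            ref_idps = set(reference.idp_names)
            child_seeds = seed_root.spawn(len(table.idp_names))
            emp_p, ref_med = {}, {}
            for idp, child in zip(table.idp_names, child_seeds):
                if idp not in ref_idps:
                    continue
                ref_dist = resample_reference_iccs(
                    reference,
                    idp,
                    subset_size=config.subset_size,
                    n_resamples=config.n_resamples,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                ref_med[idp] = float(np.nanmedian(ref_dist.icc_samples))
                obs = merged.loc[merged["idp_name"] == idp, "icc"]
                if len(obs) and np.isfinite(obs.iloc[0]):
                    emp_p[idp] = empirical_two_sided_p(float(obs.iloc[0]), ref_dist)
            merged["reference_median_icc"] = merged["idp_name"].map(ref_med)
            merged["empirical_p"] = merged["idp_name"].map(emp_p)

        merged.insert(0, "subset", subset_name)
        per_idp[subset_name] = merged

        csum = class_icc_summary(iccs)
        props = class_proportions_frame(merged)
        csum = csum.merge(props, on="class_label", how="left")
        csum.insert(0, "subset", subset_name)
        class_frames.append(csum)

        manifest["subsets"][subset_name] = {
            "sessions": sessions,
            "n_rows": int(len(merged)),
            "n_skipped": int(merged["skipped"].sum()),
            "n_significant": int(merged["significant"].fillna(False).sum()),
        }

    per_class = pd.concat(class_frames, ignore_index=True)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for subset_name, frame in per_idp.items():
            frame.to_csv(out / f"per_idp_{subset_name}.tsv", sep="\t", index=False)
        per_class.to_csv(out / "per_class.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return ReliabilityReport(per_idp=per_idp, per_class=per_class, manifest=manifest)


def class_proportions_frame(per_idp: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-class proportions of mean-effect, sphericity and normality flags.

    Denominators count estimable (non-skipped) phenotypes only; skipped
    counts are carried alongside so nothing disappears silently.
    """
    rows = []
    for label, grp in per_idp.groupby("class_label", sort=True):
        ok = grp[~grp["skipped"].astype(bool)]
        denom = len(ok)
        rows.append(
            {
                "class_label": label,
                "n_estimable": denom,
                "n_skipped_scan": int(grp["skipped"].astype(bool).sum()),
                "prop_mean_effect": (
                    float(ok["significant"].sum()) / denom if denom else np.nan
                ),
                "prop_sphericity_violated": (
                    float(ok["sphericity_violated"].sum()) / denom if denom else np.nan
                ),
                "prop_non_normal": (
                    float((ok["shapiro_p"] < alpha).sum()) / denom if denom else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def class_proportions(report: ReliabilityReport, alpha: float = 0.05) -> pd.DataFrame:
    """Proportions table across every subset of a finished report."""
    frames = []
    for subset, frame in sorted(report.per_idp.items()):
        props = class_proportions_frame(frame, alpha=alpha)
        props.insert(0, "subset", subset)
        frames.append(props)
    return pd.concat(frames, ignore_index=True)
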