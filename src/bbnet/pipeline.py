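"""Whole-study orchestration: manifest -> cleaned EEG -> spectra -> coherence
graphs -> node metrics -> group statistics -> report tables.

A study manifest lists subjects (id, group, one EEG file per state) plus a
digit-span session table. For every subject and state the pipeline cleans
the recording, computes relative band power, band coherence matrices,
thresholded graphs and the node-metric suite; it then runs the group-level
statistics: paired state contrasts (pre vs during, pre vs post) with
FDR correction and Cohen's d, power-behavior correlation maps, and the
two-way group x state ANOVA on digit-span score and completion time.
Everything is deterministic given (input files, configuration, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import behavior_scoring, io, network_metrics, preprocessing, spectral, stats
from .recording import GROUPS, STATES, EEGRecording

log = logging.getLogger("bbnet")

#: State contrasts reported by default; the during-vs-post contrast is
#: available via ``PipelineConfig.include_du_post``.
DEFAULT_CONTRASTS = (("Pre-BB", "Du-BB"), ("Pre-BB", "Post-BB"))


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable analysis parameters, with study defaults."""

    filter_low: float = 1.0
    filter_high: float = 45.0
    filter_order: int = 5
    filter_causal: bool = False
    artifact_epoch_len: float = 2.0
    artifact_amp_thresh: float = 100.0
    welch_window_len: float = 4.0
    welch_overlap: float = 2.0
    welch_nfft: int = 512
    coherence_threshold: float = 0.30
    threshold_mode: str = "absolute"
    fdr_q: float = 0.05
    alpha: float = 0.05
    include_du_post: bool = False
    bands: tuple = tuple(b.name for b in spectral.DEFAULT_BANDS)
    metrics: tuple = network_metrics.METRIC_NAMES

    def band_definitions(self):
        return tuple(b for b in spectral.DEFAULT_BANDS if b.name in self.bands)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyManifest:
    subjects: list          # dicts: {"id", "group", "eeg": {state: path}}
    config: dict
    seed: int
    digit_span: str | None
    base_dir: pathlib.Path
    states: tuple = STATES


@dataclass
class StudyReport:
    band_power: pd.DataFrame
    node_metrics: pd.DataFrame
    global_metrics: pd.DataFrame
    contrasts_global: pd.DataFrame
    contrasts_nodes: pd.DataFrame
    behavior: pd.DataFrame | None
    anova_score: stats.AnovaTable | None
    anova_time: stats.AnovaTable | None
    correlations: pd.DataFrame | None
    rejections: pd.DataFrame
    provenance: dict
    skipped_subjects: list = field(default_factory=list)


class ManifestError(ValueError):
    """Raised with a list of every schema violation found in a manifest."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid study manifest:\n- " +
                         "\n- ".join(self.violations))


def validate_manifest(path) -> StudyManifest:
    """Load and schema-check a JSON study manifest.

    Raises :class:`ManifestError` listing *every* violation found.
    """
    path = pathlib.Path(path)
    violations = []
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise
    except json.JSONDecodeError as exc:
        raise ManifestError([f"malformed JSON: {exc}"]) from exc
    if not isinstance(doc, dict):
        raise ManifestError(["manifest must be a JSON object"])
    subjects = doc.get("subjects")
    if not isinstance(subjects, list) or not subjects:
        raise ManifestError(["'subjects' must be a non-empty list"])
    states = tuple(doc.get("config", {}).get("states", STATES))
    for s in states:
        if s not in STATES:
            violations.append(f"config.states: unknown state label {s!r}")
    exclusions = set(doc.get("exclusions", []))
    seen = set()
    for i, sub in enumerate(subjects):
        label = sub.get("id", f"<subjects[{i}]>")
        if "id" not in sub:
            violations.append(f"subjects[{i}]: missing 'id'")
        elif label in seen:
            violations.append(f"subject {label!r}: duplicate id")
        seen.add(label)
        group = sub.get("group")
        if group not in GROUPS:
            violations.append(f"subject {label!r}: unknown group {group!r} "
                              f"(expected one of {GROUPS})")
        eeg = sub.get("eeg", {})
        for state in eeg:
            if state not in STATES:
                violations.append(f"subject {label!r}: unknown state "
                                  f"{state!r} in eeg files")
        if label not in exclusions:
            missing = [s for s in states if s not in eeg]
            if missing:
                violations.append(f"subject {label!r}: missing states "
                                  f"{missing} (add to 'exclusions' to skip)")
    if violations:
        raise ManifestError(violations)
    return StudyManifest(
        subjects=[s for s in subjects if s["id"] not in exclusions],
        config=doc.get("config", {}),
        seed=int(doc.get("seed", 0)),
        digit_span=doc.get("digit_span"),
        base_dir=path.parent,
        states=states,
    )


# ---------------------------------------------------------------------------
# per-recording analysis
# ---------------------------------------------------------------------------

def analyze_recording(rec: EEGRecording, config: PipelineConfig):
    """Clean one recording and compute band powers and node metrics.

    Returns ``(band_power_rows, metric_rows, rejection_report)`` where the
    row lists are long-format dict records.
    """
    clean, report = preprocessing.preprocess(
        rec, low=config.filter_low, high=config.filter_high,
        order=config.filter_order, causal=config.filter_causal,
        epoch_len=config.artifact_epoch_len,
        amp_thresh=config.artifact_amp_thresh)
    welch_kw = dict(window_len=config.welch_window_len,
                    overlap=config.welch_overlap, nfft=config.welch_nfft)
    spec = spectral.welch_psd(clean, **welch_kw)
    bands = config.band_definitions()
    power_rows = []
    for band in bands:
        rel = spectral.relative_band_power(spec, band)
        for ch, val in zip(clean.channel_labels, rel):
            power_rows.append({"subject": rec.subject_id, "group": rec.group,
                               "state": rec.state, "band": band.name,
                               "channel": ch, "rel_power": float(val)})
    matrices = spectral.all_band_coherence(clean, bands=bands, **welch_kw)
    metric_rows = []
    for band in bands:
        suite = network_metrics.metric_suite(
            matrices[band.name], tau=config.coherence_threshold,
            mode=config.threshold_mode, subject=rec.subject_id,
            state=rec.state)
        for name in config.metrics:
            table = suite["tables"][name]
            for node, value in zip(table.nodes, table.values):
                metric_rows.append({"subject": rec.subject_id,
                                    "group": rec.group, "state": rec.state,
                                    "band": band.name, "metric": name,
                                    "node": node, "value": float(value)})
    return power_rows, metric_rows, report


def _global_metrics(node_metrics: pd.DataFrame) -> pd.DataFrame:
    g = (node_metrics
         .groupby(["subject", "group", "state", "band", "metric"],
                  observed=True, sort=False)["value"]
         .mean().reset_index().rename(columns={"value": "global_mean"}))
    return g


def _contrast_pairs(states, include_du_post):
    pairs = [c for c in DEFAULT_CONTRASTS if c[0] in states and c[1] in states]
    if include_du_post and {"Du-BB", "Post-BB"} <= set(states):
        pairs.append(("Du-BB", "Post-BB"))
    return pairs


def _state_contrasts(global_metrics, node_metrics, states, config):
    """Paired t + FDR contrasts on global means and per-node values.

    Global contrasts share one FDR family per (group, contrast) across all
    metric x band tests; node-level contrasts use one family per (group,
    contrast, metric, band), i.e. the 14 channel tests corrected together.
    """
    contrasts = _contrast_pairs(states, config.include_du_post)
    global_rows, node_rows = [], []
    for group, gdf in global_metrics.groupby("group", observed=True, sort=False):
        wide = gdf.pivot_table(index="subject", columns=["state", "metric", "band"],
                               values="global_mean", observed=True)
        for pre, post in contrasts:
            pairs = {}
            for metric in config.metrics:
                for band in config.bands:
                    try:
                        x = wide[(post, metric, band)].to_frame(f"{metric}:{band}")
                        y = wide[(pre, metric, band)].to_frame(f"{metric}:{band}")
                    except KeyError:
                        continue
                    pairs[f"{metric}:{band}"] = (x, y)
            if not pairs:
                continue
            fam = stats.family_paired_tests(pairs, q=config.fdr_q)
            fam[["metric", "band"]] = fam["test"].str.split(":", expand=True)
            fam["group"] = group
            fam["contrast"] = f"{pre} vs {post}"
            global_rows.append(fam.drop(columns=["test", "unit"]))
    for (group, metric, band), mdf in node_metrics.groupby(
            ["group", "metric", "band"], observed=True, sort=False):
        wide = mdf.pivot_table(index="subject", columns=["state", "node"],
                               values="value", observed=True)
        for pre, post in contrasts:
            if pre not in wide.columns.levels[0] or post not in wide.columns.levels[0]:
                continue
            fam = stats.family_paired_tests(
                {"nodes": (wide[post], wide[pre])}, q=config.fdr_q)
            fam = fam.rename(columns={"unit": "node"}).drop(columns=["test"])
            fam["group"] = group
            fam["metric"] = metric
            fam["band"] = band
            fam["contrast"] = f"{pre} vs {post}"
            node_rows.append(fam)
    empty_g = pd.DataFrame(columns=["t", "df", "p_raw", "d", "size_label",
                                    "p_adjusted", "reject", "metric", "band",
                                    "group", "contrast"])
    empty_n = empty_g.rename(columns={"metric": "node"})
    return (pd.concat(global_rows, ignore_index=True) if global_rows else empty_g,
            pd.concat(node_rows, ignore_index=True) if node_rows else empty_n)


def _behavior_frame(sessions, group_of) -> pd.DataFrame:
    rows = []
    for s in sessions:
        final, total = behavior_scoring.score_session(s)
        rows.append({"subject": s.subject_id, "group": group_of.get(s.subject_id),
                     "state": s.state, "final_score": final,
                     "total_time_s": total,
                     "completed_rounds": behavior_scoring.truncate_session(s).completed_rounds})
    return pd.DataFrame(rows)


def _behavior_stats(behavior, band_power, config):
    """Two-way ANOVA on score/time and the power-behavior correlation maps."""
    anova_score = anova_time = None
    pre_post = behavior[behavior["state"].isin(["Pre-BB", "Post-BB"])]
    try:
        anova_score = stats.two_way_anova(pre_post["final_score"],
                                          pre_post["group"], pre_post["state"])
        anova_time = stats.two_way_anova(pre_post["total_time_s"],
                                         pre_post["group"], pre_post["state"])
    except ValueError as exc:
        log.warning("two-way ANOVA skipped: %s", exc)
    corr_rows = []
    for state in sorted(set(behavior["state"]) & {"Pre-BB", "Post-BB"}):
        beh = behavior[behavior["state"] == state].set_index("subject")
        bp = band_power[band_power["state"] == state]
        for band, bdf in bp.groupby("band", observed=True, sort=False):
            predictors = bdf.pivot_table(index="subject", columns="channel",
                                         values="rel_power", observed=True)
            common = predictors.index.intersection(beh.index)
            if len(common) < 3:
                continue
            for measure in ("final_score", "total_time_s"):
                cm = stats.correlation_map(predictors.loc[common],
                                           beh.loc[common, measure],
                                           alpha=config.alpha)
                cm = cm.rename(columns={"predictor": "channel"})
                cm["band"] = band
                cm["state"] = state
                cm["measure"] = measure
                corr_rows.append(cm)
    correlations = (pd.concat(corr_rows, ignore_index=True)
                    if corr_rows else None)
    return anova_score, anova_time, correlations


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------

def _assemble_report(power_rows, metric_rows, rejection_rows, sessions,
                     group_of, states, config, seed, skipped):
    band_power = pd.DataFrame(power_rows)
    node_metrics = pd.DataFrame(metric_rows)
    global_metrics = _global_metrics(node_metrics)
    contrasts_global, contrasts_nodes = _state_contrasts(
        global_metrics, node_metrics, states, config)
    behavior = anova_score = anova_time = correlations = None
    if sessions:
        behavior = _behavior_frame(sessions, group_of)
        anova_score, anova_time, correlations = _behavior_stats(
            behavior, band_power, config)
    provenance = {
        "config_hash": config.hash(),
        "config": asdict(config),
        "seed": seed,
        "n_subjects": int(band_power["subject"].nunique()),
        "states": list(states),
        "versions": {"bbnet": _version(), "numpy": np.__version__,
                     "pandas": pd.__version__},
        "note": ("state is treated as a between-cell factor in the two-way "
                 "ANOVA, matching the study's summary-table layout, although "
                 "it is a within-subject factor"),
    }
    return StudyReport(
        band_power=band_power, node_metrics=node_metrics,
        global_metrics=global_metrics, contrasts_global=contrasts_global,
        contrasts_nodes=contrasts_nodes, behavior=behavior,
        anova_score=anova_score, anova_time=anova_time,
        correlations=correlations,
        rejections=pd.DataFrame(rejection_rows),
        provenance=provenance, skipped_subjects=skipped)


def _version():
    try:
        from importlib.metadata import version
        return version("bbnet")
    except Exception:
        return "unknown"


def run_study(manifest: StudyManifest,
              config: PipelineConfig | None = None) -> StudyReport:
    """Run the full analysis for a manifest-described study."""
    config = config or PipelineConfig(**manifest.config.get("pipeline", {}))
    power_rows, metric_rows, rejection_rows = [], [], []
    skipped = []
    group_of = {}
    for sub in manifest.subjects:
        sid, group = sub["id"], sub["group"]
        group_of[sid] = group
        sub_power, sub_metrics, sub_rej = [], [], []
        try:
            for state in manifest.states:
                rec = io.read_recording(manifest.base_dir / sub["eeg"][state],
                                        state=state, group=group,
                                        subject_id=sid)
                p, m, rep = analyze_recording(rec, config)
                sub_power += p
                sub_metrics += m
                sub_rej.append({"subject": sid, "state": state,
                                "n_epochs": rep.n_epochs_total,
                                "n_rejected": rep.n_epochs_rejected,
                                "fraction": rep.rejection_fraction})
        except (OSError, KeyError, ValueError) as exc:
            log.warning("skipping subject %s: %s", sid, exc)
            skipped.append(sid)
            continue
        power_rows += sub_power
        metric_rows += sub_metrics
        rejection_rows += sub_rej
        log.info("analyzed subject %s (%d states)", sid, len(manifest.states))
    if len(skipped) > len(manifest.subjects) / 2:
        raise RuntimeError(f"more than half of the subjects were skipped "
                           f"({len(skipped)}/{len(manifest.subjects)})")
    sessions = []
    if manifest.digit_span:
        sessions = behavior_scoring.read_sessions_tsv(
            manifest.base_dir / manifest.digit_span)
    return _assemble_report(power_rows, metric_rows, rejection_rows, sessions,
                            group_of, manifest.states, config, manifest.seed,
                            skipped)


def run_simulated_study(study_cfg, config: PipelineConfig | None = None,
                        with_behavior=True) -> StudyReport:
    """Simulate a study (see :mod:`bbnet.synthetic_data`) and analyze it.

    Recordings are generated and analyzed one at a time, so memory stays flat
    regardless of study size.
    """
    from . import synthetic_data

    config = config or PipelineConfig()
    power_rows, metric_rows, rejection_rows = [], [], []
    group_of = {}
    for rec in synthetic_data.iter_study_recordings(study_cfg):
        p, m, rep = analyze_recording(rec, config)
        power_rows += p
        metric_rows += m
        group_of[rec.subject_id] = rec.group
        rejection_rows.append({"subject": rec.subject_id, "state": rec.state,
                               "n_epochs": rep.n_epochs_total,
                               "n_rejected": rep.n_epochs_rejected,
                               "fraction": rep.rejection_fraction})
    sessions = (synthetic_data.simulate_behavior(study_cfg)
                if with_behavior else [])
    return _assemble_report(power_rows, metric_rows, rejection_rows, sessions,
                            group_of, study_cfg.states, config,
                            study_cfg.seed, skipped=[])


def write_report(report: StudyReport, out_dir) -> None:
    """Write every report table as TSV plus a JSON provenance summary."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "band_power.tsv": report.band_power,
        "node_metrics.tsv": report.node_metrics,
        "global_metrics.tsv": report.global_metrics,
        "contrasts_global.tsv": report.contrasts_global,
        "contrasts_nodes.tsv": report.contrasts_nodes,
        "rejections.tsv": report.rejections,
    }
    if report.behavior is not None:
        tables["behavior.tsv"] = report.behavior
    if report.correlations is not None:
        tables["correlations.tsv"] = report.correlations
    for name, df in tables.items():
        io.write_table(df, out_dir / name)
    summary = {"provenance": report.provenance,
               "skipped_subjects": report.skipped_subjects}
    for label, aov in (("anova_score", report.anova_score),
                       ("anova_time", report.anova_time)):
        if aov is not None:
            aov.table.reset_index(names="effect").to_csv(
                out_dir / f"{label}.tsv", sep="\t", index=False)
            summary[label] = json.loads(
                aov.table.to_json(orient="index"))
    with open(out_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
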