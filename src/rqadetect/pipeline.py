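"""End-to-end orchestration: blocks, cases, features, selection, evaluation.

Each 23.6 s segment is split into 16 non-overlapping blocks of 1.475 s
(256 samples at 173.61 Hz; the trailing remainder sample is dropped), a
twelve-measure recurrence feature vector is extracted per block, and the
five clinical classification cases are assembled from the subset labels:

=====  =========================================================
Case   Classes
=====  =========================================================
I      healthy {A, B} vs interictal {C, D} vs ictal {E}
II     healthy {A} vs interictal {D} vs ictal {E}
III    healthy {A} vs ictal {E}
IV     nonseizure {A, B, C, D} vs seizure {E}
V      interictal {D} vs ictal {E}
=====  =========================================================

Each case is scored by the repeated-sub-sampling neural-network harness,
by default with mRMR feature selection re-run on the training portion of
every repeat (a ``global`` scope reproducing one selection on all data is
available in the config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierSpec, EvalProtocol, EvalReport, train_eval
from .embedding import EmbeddingParams, estimate_embedding
from .measures import (FEATURE_NAMES, EmbeddingOptions, FeatureConfig,
                       RecurrenceOptions, RQAConfig, extract_features)
from .mrmr import FeatureDataset, mrmr_select
from .signals import (DEFAULT_RATE, SEGMENT_LEN, SurrogateSpec, TimeSeries,
                      gen_surrogate_subsets, read_bonn_dir)

logger = logging.getLogger(__name__)

BLOCK_DURATION_S = 1.475
"""Block duration in seconds (256 samples at 173.61 Hz)."""


@dataclass(frozen=True)
class CaseDefinition:
    """A classification case: which subsets go into which class."""

    name: str
    class_map: dict[str, str]  # subset label -> class name

    def __post_init__(self) -> None:
        bad = set(self.class_map) - set("ABCDE")
        if bad:
            raise ValueError(f"case {self.name}: unknown subsets {sorted(bad)}")
        if len(set(self.class_map.values())) < 2:
            raise ValueError(f"case {self.name}: needs at least 2 classes")

    @property
    def subsets(self) -> tuple[str, ...]:
        return tuple(sorted(self.class_map))


CASES: dict[str, CaseDefinition] = {
    "I": CaseDefinition("I", {"A": "healthy", "B": "healthy",
                              "C": "interictal", "D": "interictal",
                              "E": "ictal"}),
    "II": CaseDefinition("II", {"A": "healthy", "D": "interictal",
                                "E": "ictal"}),
    "III": CaseDefinition("III", {"A": "healthy", "E": "ictal"}),
    "IV": CaseDefinition("IV", {"A": "nonseizure", "B": "nonseizure",
                                "C": "nonseizure", "D": "nonseizure",
                                "E": "seizure"}),
    "V": CaseDefinition("V", {"D": "interictal", "E": "ictal"}),
}


def segment_blocks(series: TimeSeries,
                   block_dur: float = BLOCK_DURATION_S) -> list[TimeSeries]:
    """Split a segment into consecutive non-overlapping blocks.

    The block length is ``floor(block_dur * rate)`` samples and any
    trailing remainder is dropped (a 4097-sample segment yields 16 blocks
    of 256 samples and drops one sample).
    """
    if not block_dur > 0:
        raise ValueError("block_dur must be positive")
    n_block = int(block_dur * series.rate)
    if n_block < 1:
        raise ValueError("block duration shorter than one sample")
    n = len(series)
    if n < n_block:
        raise ValueError(
            f"series of {n} samples is shorter than one block ({n_block})")
    return [TimeSeries(series.samples[i * n_block:(i + 1) * n_block],
                       rate=series.rate, label=series.label)
            for i in range(n // n_block)]


def features_table(subsets: dict[str, list[TimeSeries]],
                   cfg: FeatureConfig | None = None,
                   block_dur: float = BLOCK_DURATION_S) -> pd.DataFrame:
    """Extract the per-block feature table for every subset.

    Returns a DataFrame with columns ``subset, segment_id, block_idx``
    followed by the twelve measures and a ``flags`` column.  In global
    embedding mode without fixed (tau, m), the parameters are estimated
    once from a sample of blocks (median tau and m over 12 blocks drawn
    across subsets) and applied everywhere.
    """
    cfg = cfg or FeatureConfig()
    params: EmbeddingParams | None = None
    if cfg.embedding.mode == "global":
        if cfg.embedding.tau is not None and cfg.embedding.m is not None:
            params = EmbeddingParams(cfg.embedding.tau, cfg.embedding.m)
        else:
            params = _global_embedding(subsets, cfg, block_dur)
            logger.info("global embedding: tau=%d m=%d", params.tau, params.m)
    rows = []
    for label in sorted(subsets):
        for seg_id, seg in enumerate(subsets[label]):
            for blk_idx, blk in enumerate(segment_blocks(seg, block_dur)):
                fv = extract_features(blk, cfg, params=params,
                                      segment_id=seg_id, block_idx=blk_idx)
                row = {"subset": label, "segment_id": seg_id,
                       "block_idx": blk_idx}
                row.update({name: getattr(fv, name)
                            for name in FEATURE_NAMES})
                row["flags"] = ";".join(fv.flags)
                rows.append(row)
    return pd.DataFrame(rows)


def _global_embedding(subsets, cfg: FeatureConfig,
                      block_dur: float) -> EmbeddingParams:
    emb = cfg.embedding
    taus, ms = [], []
    labels = sorted(subsets)
    for label in labels:
        for seg in subsets[label][: max(1, 12 // len(labels))]:
            blk = segment_blocks(seg, block_dur)[0]
            p = estimate_embedding(blk, max_lag=emb.max_lag,
                                   n_bins=emb.n_bins, m_max=emb.m_max,
                                   saturation_tol=emb.saturation_tol)
            taus.append(p.tau)
            ms.append(p.m)
    return EmbeddingParams(tau=int(np.median(taus)), m=int(np.median(ms)))


def dataset_from_table(table: pd.DataFrame,
                       case: CaseDefinition) -> FeatureDataset:
    """Select the case's subsets from a feature table and attach labels."""
    missing = [s for s in case.subsets if s not in set(table["subset"])]
    if missing:
        raise ValueError(
            f"case {case.name}: subsets {missing} absent from the table")
    sub = table[table["subset"].isin(case.subsets)].reset_index(drop=True)
    class_names = tuple(sorted(set(case.class_map.values())))
    y = np.array([class_names.index(case.class_map[s])
                  for s in sub["subset"]])
    X = sub[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return FeatureDataset(X, y, FEATURE_NAMES, class_names)


def assemble_case(subsets: dict[str, list[TimeSeries]], case: CaseDefinition,
                  cfg: FeatureConfig | None = None,
                  block_dur: float = BLOCK_DURATION_S) -> FeatureDataset:
    """Segment, extract and label the feature dataset for one case."""
    missing = [s for s in case.subsets if s not in subsets]
    if missing:
        raise ValueError(f"case {case.name}: missing subsets {missing}")
    table = features_table({s: subsets[s] for s in case.subsets}, cfg,
                           block_dur)
    return dataset_from_table(table, case)


# ---------------------------------------------------------------------------
# full-run configuration and orchestration


@dataclass(frozen=True)
class MRMRSettings:
    k: int = 5
    beta: float | None = None      # None: mean-redundancy 1/|S|
    n_bins: int = 3
    scope: str = "train"           # "train" (per-repeat) | "global"


@dataclass(frozen=True)
class DataSettings:
    source: str = "surrogate"      # "surrogate" | "bonn"
    path: str | None = None        # directory for source == "bonn"
    n_segments: int = 100
    segment_len: int = SEGMENT_LEN
    rate: float = DEFAULT_RATE
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    data: DataSettings = field(default_factory=DataSettings)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    mrmr: MRMRSettings = field(default_factory=MRMRSettings)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    eval: EvalProtocol = field(default_factory=EvalProtocol)
    block_dur: float = BLOCK_DURATION_S
    cases: tuple[str, ...] = ("I", "II", "III", "IV", "V")
    output_dir: str = "rqadetect_out"


def _build(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(payload) - names
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    return cls(**payload)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file and/or a dict.

    The YAML mirrors the dataclass tree::

        data:       {source: surrogate, n_segments: 100, seed: 0}
        embedding:  {m_max: 10, mode: per_block}
        recurrence: {target_rr: 0.10}
        rqa:        {l_min: 2, v_min: 2}
        mrmr:       {k: 5, scope: train}
        classifier: {hidden_units: 20}
        eval:       {n_repeats: 20, seed: 0}
        cases:      [I, II, III, IV, V]
        output_dir: out
    """
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    if overrides:
        payload = {**payload, **overrides}
    kwargs: dict = {}
    if "data" in payload:
        kwargs["data"] = _build(DataSettings, payload["data"])
    feat_kwargs: dict = {}
    if "embedding" in payload:
        feat_kwargs["embedding"] = _build(EmbeddingOptions,
                                          payload["embedding"])
    if "recurrence" in payload:
        feat_kwargs["recurrence"] = _build(RecurrenceOptions,
                                           payload["recurrence"])
    if "rqa" in payload:
        feat_kwargs["rqa"] = _build(RQAConfig, payload["rqa"])
    if feat_kwargs:
        kwargs["features"] = FeatureConfig(**feat_kwargs)
    if "mrmr" in payload:
        kwargs["mrmr"] = _build(MRMRSettings, payload["mrmr"])
    if "classifier" in payload:
        kwargs["classifier"] = _build(ClassifierSpec, payload["classifier"])
    if "eval" in payload:
        kwargs["eval"] = _build(EvalProtocol, payload["eval"])
    for key in ("block_dur", "output_dir"):
        if key in payload:
            kwargs[key] = payload[key]
    if "cases" in payload:
        kwargs["cases"] = tuple(str(c) for c in payload["cases"])
    return PipelineConfig(**kwargs)


def load_subsets(cfg: PipelineConfig) -> dict[str, list[TimeSeries]]:
    """Materialize the input data named by the config."""
    d = cfg.data
    if d.source == "surrogate":
        spec = SurrogateSpec(n_segments=d.n_segments,
                             segment_len=d.segment_len, rate=d.rate,
                             seed=d.seed)
        return gen_surrogate_subsets(spec)
    if d.source == "bonn":
        if not d.path:
            raise ValueError("data.source is 'bonn' but data.path is unset")
        return read_bonn_dir(d.path, rate=d.rate)
    raise ValueError(f"unknown data source {d.source!r}")


def evaluate_case(ds: FeatureDataset, case_name: str,
                  cfg: PipelineConfig) -> EvalReport:
    """Select features and run the NN evaluation for one assembled case."""
    m = cfg.mrmr
    if m.scope == "global":
        sel = mrmr_select(ds, k=m.k, beta=m.beta, n_bins=m.n_bins)
        return train_eval(ds, selected=sel.order, clf=cfg.classifier,
                          proto=cfg.eval, case=case_name)
    if m.scope != "train":
        raise ValueError(f"unknown mrmr scope {m.scope!r}")

    def selector(train_ds: FeatureDataset):
        return mrmr_select(train_ds, k=m.k, beta=m.beta,
                           n_bins=m.n_bins).order

    return train_eval(ds, selector=selector, clf=cfg.classifier,
                      proto=cfg.eval, case=case_name)


def run_full(cfg: PipelineConfig,
             write_outputs: bool = True) -> dict[str, EvalReport]:
    """Execute the whole pipeline and (optionally) write its artifacts.

    Writes ``features.csv``, one global ``selection_<case>.csv`` when the
    selection scope is global, and ``report_<case>.json`` per case, into
    ``cfg.output_dir``.  Returns the reports keyed by case name.
    """
    unknown = [c for c in cfg.cases if c not in CASES]
    if unknown:
        raise ValueError(f"unknown cases requested: {unknown}")
    subsets = load_subsets(cfg)
    needed = sorted({s for c in cfg.cases for s in CASES[c].subsets})
    missing = [s for s in needed if s not in subsets]
    if missing:
        raise ValueError(f"data source lacks subsets {missing}")

    table = features_table(subsets, cfg.features, cfg.block_dur)
    out = Path(cfg.output_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        cols = ["subset", "segment_id", "block_idx", *FEATURE_NAMES, "flags"]
        table[cols].to_csv(out / "features.csv", index=False)

    reports: dict[str, EvalReport] = {}
    for case_name in cfg.cases:
        case = CASES[case_name]
        ds = dataset_from_table(table, case)
        if write_outputs and cfg.mrmr.scope == "global":
            sel = mrmr_select(ds, k=cfg.mrmr.k, beta=cfg.mrmr.beta,
                              n_bins=cfg.mrmr.n_bins)
            sel.to_frame().to_csv(out / f"selection_{case_name}.csv",
                                  index=False)
        report = evaluate_case(ds, case_name, cfg)
        reports[case_name] = report
        if write_outputs:
            with open(out / f"report_{case_name}.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
        logger.info("case %s: %.2f%% +/- %.2f%%", case_name, report.mean,
                    report.sd)
    return reports
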