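"""High-level training workflow and on-disk model archives.

A trained model bundles the feature schema (with normalization bounds), the
optional graph feature index, the five fold forests with their validation
score distributions, and the FPR calibration table. Archives are
directories holding JSON for everything tabular and one joblib blob per
fold forest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd

from .ensemble import (
    CalibrationTable,
    FractileForestClassifier,
    tune_num_trees,
    permutation_importance,
)
from .features import (
    FeatureSchema,
    apply_normalizer,
    assemble_feature_matrix,
    fit_normalizer,
)
from .graph import (
    GraphFeatureIndex,
    GraphFeatureSelector,
    GraphParams,
    encode_graph_matrix,
)
from .records import TranscriptRecord
from .tracks import AnnotationBundle

ARCHIVE_VERSION = 1

# Canonical display names and column order of the three shipped classifiers.
MODEL_COLUMNS = {
    "cp-pcg": "pcg_circRNA",
    "cp-lncrna": "lncRNA_circRNA",
    "sp-circrna": "stem_cell_circRNA",
}
MODEL_ORDER = tuple(MODEL_COLUMNS)


@dataclass
class TrainedModel:
    """A fully trained classifier: features, ensemble and calibration."""

    name: str
    schema: FeatureSchema
    ensemble: FractileForestClassifier
    calibration: Optional[CalibrationTable] = None
    graph_index: Optional[GraphFeatureIndex] = None
    report: Dict = field(default_factory=dict)

    @property
    def profile(self) -> str:
        return self.schema.profile

    def feature_matrix(self, records: Sequence[TranscriptRecord],
                       annotations: Optional[AnnotationBundle] = None
                       ) -> np.ndarray:
        raw, _ = assemble_feature_matrix(
            records, annotations=annotations, graph_index=self.graph_index,
            profile=self.profile)
        return apply_normalizer(raw, self.schema)

    def predict_records(self, records: Sequence[TranscriptRecord],
                        annotations: Optional[AnnotationBundle] = None
                        ) -> pd.DataFrame:
        """Per-record mean fractile, display score (%) and FPR."""
        X = self.feature_matrix(records, annotations)
        mf = self.ensemble.predict_mean_fractile(X)
        fpr = (self.calibration.lookup(mf) if self.calibration is not None
               else np.full(mf.shape, np.nan))
        return pd.DataFrame({
            "id": [r.id for r in records],
            "mean_fractile": mf,
            "score": [f"{round(v * 100):d}%" for v in mf],
            "fpr": np.round(np.atleast_1d(fpr), 4),
        })

    def save(self, outdir: Union[str, Path]) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ens = self.ensemble
        manifest = {
            "version": ARCHIVE_VERSION,
            "name": self.name,
            "profile": self.profile,
            "n_estimators": ens.n_estimators,
            "n_folds": ens.n_folds,
            "random_state": ens.random_state,
            "n_features": int(ens.n_features_in_),
            "classes": [int(c) for c in ens.classes_],
            "report": self.report,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
        (outdir / "schema.json").write_text(self.schema.to_json())
        if self.graph_index is not None:
            (outdir / "graph_index.json").write_text(self.graph_index.to_json())
        if self.calibration is not None:
            (outdir / "calibration.json").write_text(self.calibration.to_json())
        (outdir / "val_scores.json").write_text(json.dumps(
            [vs.tolist() for vs in ens.val_scores_]))
        for k, forest in enumerate(ens.models_):
            joblib.dump(forest, outdir / f"fold_{k}.joblib")
        return outdir

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"unsupported archive version {manifest.get('version')!r}")
        schema = FeatureSchema.from_json((path / "schema.json").read_text())
        ens = FractileForestClassifier(
            n_estimators=manifest["n_estimators"],
            n_folds=manifest["n_folds"],
            random_state=manifest["random_state"])
        ens.models_ = [joblib.load(path / f"fold_{k}.joblib")
                       for k in range(manifest["n_folds"])]
        ens.val_scores_ = [np.asarray(vs) for vs in json.loads(
            (path / "val_scores.json").read_text())]
        ens.classes_ = np.asarray(manifest["classes"])
        ens.n_features_in_ = manifest["n_features"]
        graph_index = None
        if (path / "graph_index.json").exists():
            graph_index = GraphFeatureIndex.from_json(
                (path / "graph_index.json").read_text())
        calibration = None
        if (path / "calibration.json").exists():
            calibration = CalibrationTable.from_json(
                (path / "calibration.json").read_text())
            ens.calibration_ = calibration
        return cls(name=manifest["name"], schema=schema, ensemble=ens,
                   calibration=calibration, graph_index=graph_index,
                   report=manifest.get("report", {}))


def train_model(pos: Sequence[TranscriptRecord],
                neg: Sequence[TranscriptRecord],
                name: str = "custom",
                profile: str = "sequence_only",
                annotations: Optional[AnnotationBundle] = None,
                n_trees: Union[int, str] = "auto",
                top_k: int = 101,
                graph_params: GraphParams = GraphParams(),
                calibration_negatives: Optional[Sequence[TranscriptRecord]] = None,
                calibration_fraction: float = 0.2,
                seed: Optional[int] = 0,
                rank_importance: bool = True) -> TrainedModel:
    """Run the full training workflow on labeled records.

    Steps: graph-feature selection (profiles other than gc_len), feature
    assembly, normalization-bound fitting, tree-count tuning (``n_trees ==
    "auto"`` searches 10..100 step 10), five-fold ensemble training, and
    FPR calibration. Calibration negatives default to a held-out
    ``calibration_fraction`` split of ``neg``; pass
    ``calibration_negatives`` to use an independent set instead.
    """
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)

    if calibration_negatives is None:
        n_cal = max(1, int(round(len(neg) * calibration_fraction)))
        if len(neg) - n_cal < 5:
            raise ValueError("too few negatives to hold out a calibration split")
        order = rng.permutation(len(neg))
        calibration_negatives = [neg[i] for i in order[:n_cal]]
        neg = [neg[i] for i in order[n_cal:]]

    records = list(pos) + list(neg)
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])

    graph_index = None
    graph_counts = None
    if profile != "gc_len":
        graph_counts = encode_graph_matrix(
            [r.sequence for r in records], graph_params)
        selector = GraphFeatureSelector(
            radius=graph_params.radius, distance=graph_params.distance,
            hash_dim=graph_params.hash_dim, hash_seed=graph_params.hash_seed,
            top_k=top_k,
            random_state=None if seed is None else (int(seed) * 31 + 5) % (2 ** 31))
        selector.fit_encoded(graph_counts, y)
        graph_index = selector.index_

    raw, schema = assemble_feature_matrix(
        records, annotations=annotations, graph_index=graph_index,
        profile=profile, graph_counts=graph_counts)
    schema = fit_normalizer(raw, schema)
    X = apply_normalizer(raw, schema)

    if n_trees == "auto":
        n_trees = tune_num_trees(X, y, seed=seed)
    n_trees = int(n_trees)

    ensemble = FractileForestClassifier(
        n_estimators=n_trees, random_state=seed).fit(X, y)

    raw_cal, _ = assemble_feature_matrix(
        calibration_negatives, annotations=annotations,
        graph_index=graph_index, profile=profile)
    ensemble.calibrate(X_neg=apply_normalizer(raw_cal, schema))

    report = {
        "n_trees": n_trees,
        "cv_auc": round(float(ensemble.cv_auc_), 4),
        "fold_aucs": [round(float(a), 4) for a in ensemble.fold_aucs_],
        "n_pos": len(pos),
        "n_neg": len(neg),
        "n_calibration_negatives": len(calibration_negatives),
        "profile": profile,
        "seed": seed,
    }
    if rank_importance:
        imp = permutation_importance(
            ensemble.models_[0], X[ensemble.fold_assignment_ != 0],
            (y == 1).astype(int)[ensemble.fold_assignment_ != 0],
            seed=seed)
        top = np.argsort(-imp)[:10]
        report["top_features"] = [
            {"name": schema.names[i], "importance": round(float(imp[i]), 6)}
            for i in top]

    return TrainedModel(name=name, schema=schema, ensemble=ensemble,
                        calibration=ensemble.calibration_,
                        graph_index=graph_index, report=report)


def predict_table(models: Sequence[TrainedModel],
                  records: Sequence[TranscriptRecord],
                  annotations: Optional[AnnotationBundle] = None
                  ) -> pd.DataFrame:
    """Fig-6-style prediction table: one row per input, per-model score + FPR.

    Model columns follow the fixed order pcg_circRNA, lncRNA_circRNA,
    stem_cell_circRNA; custom-named models append after, in given order.
    """
    def sort_key(m: TrainedModel):
        return (MODEL_ORDER.index(m.name) if m.name in MODEL_ORDER
                else len(MODEL_ORDER))

    models = sorted(models, key=sort_key)
    out = pd.DataFrame({"id": [r.id for r in records]})
    positions = [
        f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}"
        f"({r.interval.strand})" if r.interval is not None else "."
        for r in records]
    out["position"] = positions
    for model in models:
        col = MODEL_COLUMNS.get(model.name, model.name)
        table = model.predict_records(records, annotations)
        out[f"{col}_score"] = table["score"].values
        out[f"{col}_fpr"] = table["fpr"].values
    return out
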