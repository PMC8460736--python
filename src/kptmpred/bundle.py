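"""On-disk model bundles.

A fitted :class:`~kptmpred.model.MultiLabelKPTMClassifier` serializes to
a directory of inspectable parts: the positive/negative coupling tables
as JSON, the standardization parameters as JSON, the per-PTM selected
column indices as JSON, one pickled SVM per PTM type, and a config
manifest identifying the estimator parameters and package version.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np

from . import __version__
from .alphabet import PTM_TYPES
from .encoders import CouplingModel, EnsembleEncoder, SequenceCouplingEncoder
from .model import MultiLabelKPTMClassifier

MANIFEST_NAME = "manifest.json"


def save_bundle(clf: MultiLabelKPTMClassifier, outdir: str | Path) -> Path:
    """Write a fitted classifier to ``outdir``; returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    feat = clf.featurizer_

    coupling = {}
    for name, enc in feat.encoders_:
        if name == "coupling":
            coupling = {
                "positive": json.loads(enc.positive_model_.to_json()),
                "negative": json.loads(enc.negative_model_.to_json()),
            }
    (outdir / "coupling.json").write_text(json.dumps(coupling))

    scaler = {}
    if feat.standardize:
        scaler = {"mean": feat.scaler_.mean_.tolist(),
                  "scale": feat.scaler_.scale_.tolist(),
                  "var": feat.scaler_.var_.tolist()}
    (outdir / "scaler.json").write_text(json.dumps(scaler))

    (outdir / "supports.json").write_text(json.dumps(
        {ptm: clf.supports_[ptm].tolist() for ptm in PTM_TYPES}))

    for ptm in PTM_TYPES:
        with open(outdir / f"svm_{ptm}.pkl", "wb") as fh:
            pickle.dump(clf.classifiers_[ptm], fh)

    manifest = {
        "package_version": __version__,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in clf.get_params().items() if k != "support"},
        "feature_names": feat.feature_names_out_.tolist(),
    }
    (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    return outdir


def load_bundle(bundle_dir: str | Path) -> MultiLabelKPTMClassifier:
    """Reassemble a fitted classifier from :func:`save_bundle` output."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / MANIFEST_NAME).read_text())
    params = dict(manifest["params"])
    for key in ("encoders", "k_values"):
        if key in params:
            params[key] = tuple(params[key])
    clf = MultiLabelKPTMClassifier(**params)

    feat = EnsembleEncoder(zeta=clf.zeta, encoders=clf.encoders,
                           k_values=clf.k_values, pseudocount=clf.pseudocount)
    feat.encoders_ = feat._make_encoders()
    coupling = json.loads((bundle_dir / "coupling.json").read_text())
    for name, enc in feat.encoders_:
        if name == "coupling":
            enc.positive_model_ = CouplingModel.from_json(
                json.dumps(coupling["positive"]))
            enc.negative_model_ = CouplingModel.from_json(
                json.dumps(coupling["negative"]))
            enc.n_features_out_ = 2 * clf.zeta
    feat.feature_names_out_ = np.asarray(manifest["feature_names"],
                                         dtype=object)
    feat.n_features_out_ = len(feat.feature_names_out_)
    scaler = json.loads((bundle_dir / "scaler.json").read_text())
    if scaler:
        from sklearn.preprocessing import StandardScaler

        ss = StandardScaler()
        ss.mean_ = np.asarray(scaler["mean"])
        ss.scale_ = np.asarray(scaler["scale"])
        ss.var_ = np.asarray(scaler["var"])
        ss.n_features_in_ = ss.mean_.size
        feat.scaler_ = ss
    else:
        feat.standardize = False
    clf.featurizer_ = feat

    supports = json.loads((bundle_dir / "supports.json").read_text())
    clf.supports_ = {ptm: np.asarray(idx, dtype=int)
                     for ptm, idx in supports.items()}
    clf.classifiers_ = {}
    for ptm in PTM_TYPES:
        with open(bundle_dir / f"svm_{ptm}.pkl", "rb") as fh:
            clf.classifiers_[ptm] = pickle.load(fh)
    clf.n_features_in_ = 2 * clf.zeta + 1
    return clf
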