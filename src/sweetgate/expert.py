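"""The similarity-gated consensus expert system and its applicability domain.

Workflow for a query molecule:

1. compute its fingerprint and its average Jaccard-Tanimoto distances d_s1,
   d_s2 to the two sweet reference clusters;
2a. if the distances fall below the cluster thresholds (0.6 for S1, 0.8 for
    S2), classify it as **sweet** by structural similarity (gate pathway);
2b. otherwise predict it with the strict consensus of the N3 and PLSDA
    models trained on the molecules outside the reference clusters: the two
    classifiers must agree, or the molecule is **not-assigned**.

The literal reading of step 2a is an AND over both clusters, while the
stated justification ("similarity to sweet molecules of clusters S1 *or*
S2") implies OR; both combination rules are implemented (``gate_rule`` of
``"any"`` — the default — or ``"all"``), with strict inequality at the
thresholds.

Applicability domain: gate-path molecules are in-domain by construction;
consensus-path molecules are checked on two branches — leverage in PLSDA
score space against h* = 3·n_lv/n_train, and average similarity to the N3
training set against a low percentile of the training self-similarities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    DescriptorTable,
    FingerprintMatrix,
    FingerprintParams,
    NOT_ASSIGNED,
    SWEET,
)
from .metrics import ValidationReport, class_metrics, monte_carlo_validate
from .model_selection import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_LV_GRID,
    optimize_hyperparameter,
)
from .n3 import N3Classifier
from .plsda import PLSDAClassifier
from .similarity import (
    ClusterReference,
    average_cluster_distance,
    discover_sweet_clusters,
)

GATE_S1 = "gate_S1"
GATE_S2 = "gate_S2"
CONSENSUS = "consensus"


def consensus_predict(class_n3: str, class_pls: str) -> str:
    """Strict consensus: the common class on agreement, otherwise not-assigned."""
    if class_n3 == class_pls and class_n3 != NOT_ASSIGNED:
        return class_n3
    return NOT_ASSIGNED


@dataclass
class ExpertPrediction:
    """Final verdict for one molecule, with its decision pathway and AD evidence."""

    id: str
    class_label: str
    pathway: str
    d_s1: float | None = None
    d_s2: float | None = None
    n3_class: str | None = None
    n3_score_sweet: float | None = None
    plsda_class: str | None = None
    in_ad: bool | None = None
    leverage: float | None = None
    h_star: float | None = None
    leverage_ok: bool | None = None
    similarity_ok: bool | None = None
    error: str | None = None


def predictions_frame(predictions: list[ExpertPrediction]) -> pd.DataFrame:
    """Predictions as the standard output table."""
    rows = []
    for p in predictions:
        d = asdict(p)
        d["class"] = d.pop("class_label")
        rows.append(d)
    columns = ["id", "class", "pathway", "d_s1", "d_s2", "n3_class",
               "n3_score_sweet", "plsda_class", "in_ad", "leverage", "h_star",
               "leverage_ok", "similarity_ok", "error"]
    return pd.DataFrame(rows, columns=columns)


class SweetTasteExpertSystem:
    """Similarity gate + strict N3/PLSDA consensus with applicability domain.

    Parameters
    ----------
    s1_threshold, s2_threshold : float
        Average-distance cutoffs of the two sweet reference clusters.
    gate_rule : {'any', 'all'}
        Whether one satisfied cluster suffices ('any', default) or both
        cutoffs must hold ('all').
    alpha, n_lv : hyperparameters of the component classifiers; when
        ``optimize=True`` they are re-tuned by venetian-blinds CV on the
        consensus training set (alpha grid 0.5..3.0, LV grid 1..10).
    ad_percentile : float
        Percentile of training self-similarities used as the N3 AD cutoff.
    ad_rule : {'both', 'either'}
        Whether a consensus-path molecule must pass both AD branches or one.
    """

    def __init__(
        self,
        fingerprint_params: FingerprintParams | None = None,
        s1_threshold: float = 0.6,
        s2_threshold: float = 0.8,
        gate_rule: str = "any",
        alpha: float = 1.5,
        n_lv: int = 1,
        optimize: bool = False,
        alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
        lv_grid: tuple[int, ...] = DEFAULT_LV_GRID,
        ad_percentile: float = 5.0,
        ad_rule: str = "both",
        cv_groups: int = 5,
        cluster_seed: int = 0,
    ):
        if gate_rule not in ("any", "all"):
            raise ValueError("gate_rule must be 'any' or 'all'")
        if ad_rule not in ("both", "either"):
            raise ValueError("ad_rule must be 'both' or 'either'")
        self.fingerprint_params = fingerprint_params or FingerprintParams()
        self.s1_threshold = s1_threshold
        self.s2_threshold = s2_threshold
        self.gate_rule = gate_rule
        self.alpha = alpha
        self.n_lv = n_lv
        self.optimize = optimize
        self.alpha_grid = alpha_grid
        self.lv_grid = lv_grid
        self.ad_percentile = ad_percentile
        self.ad_rule = ad_rule
        self.cv_groups = cv_groups
        self.cluster_seed = cluster_seed

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        fingerprints: FingerprintMatrix,
        descriptors: DescriptorTable,
        y,
        cluster_references: list[ClusterReference] | None = None,
    ) -> "SweetTasteExpertSystem":
        """Train gate references and the consensus classifiers.

        ``cluster_references=None`` discovers sweet clusters from the
        training fingerprints; an explicit empty list disables the gate
        (pure consensus).  Rows of ``descriptors`` are matched to
        ``fingerprints.ids`` by id.
        """
        y = np.asarray(y, dtype=object)
        if y.size != fingerprints.n_molecules:
            raise ValueError("labels do not match fingerprint rows")
        if cluster_references is None:
            cluster_references = discover_sweet_clusters(
                fingerprints,
                y,
                thresholds=(self.s1_threshold, self.s2_threshold),
                seed=self.cluster_seed,
            )
        self.references_ = list(cluster_references)

        gate_mask = np.array(
            [self._gate_outcome(fp)[0] is not None for fp in fingerprints.bits]
        )
        consensus_idx = np.where(~gate_mask)[0]
        if consensus_idx.size == 0:
            raise ValueError("gate routed every training molecule; nothing to train on")
        desc_index = {mol_id: i for i, mol_id in enumerate(descriptors.ids)}
        rows = []
        for i in consensus_idx:
            mol_id = fingerprints.ids[i]
            if mol_id not in desc_index:
                raise ValueError(f"descriptor row missing for training molecule {mol_id}")
            rows.append(desc_index[mol_id])
        X = descriptors.values[rows]
        y_c3 = y[consensus_idx]
        if np.unique(y_c3).size < 2:
            raise ValueError("consensus training set lost a class")

        alpha, n_lv = self.alpha, self.n_lv
        if self.optimize:
            alpha = optimize_hyperparameter(
                X, y_c3, N3Classifier(), "alpha", self.alpha_grid,
                self.cv_groups, prefer="larger",
            ).best_value
            n_lv = optimize_hyperparameter(
                X, y_c3, PLSDAClassifier(), "n_lv", self.lv_grid,
                self.cv_groups, prefer="smaller",
            ).best_value
        self.alpha_, self.n_lv_ = alpha, n_lv
        self.n3_ = N3Classifier(alpha=alpha).fit(X, y_c3)
        self.plsda_ = PLSDAClassifier(n_lv=n_lv).fit(X, y_c3)
        self.descriptor_names_ = list(descriptors.names)
        self.similarity_cutoff_ = float(
            np.percentile(self.n3_.training_self_similarity(), self.ad_percentile)
        )
        self.train_ids_ = list(fingerprints.ids)
        return self

    # ----------------------------------------------------------------- gate

    def _distances(self, fp: np.ndarray) -> tuple[float | None, float | None]:
        d = [average_cluster_distance(fp, ref) for ref in self.references_]
        d1 = d[0] if len(d) >= 1 else None
        d2 = d[1] if len(d) >= 2 else None
        return d1, d2

    def _gate_outcome(self, fp: np.ndarray) -> tuple[str | None, float | None, float | None]:
        """(pathway or None, d_s1, d_s2); pathway is the satisfied cluster (S1 first)."""
        if not getattr(self, "references_", None):
            return None, None, None
        d1, d2 = self._distances(fp)
        hits = []
        if d1 is not None and d1 < self.references_[0].threshold:
            hits.append(GATE_S1)
        if d2 is not None and d2 < self.references_[1].threshold:
            hits.append(GATE_S2)
        if self.gate_rule == "any":
            return (hits[0] if hits else None), d1, d2
        required = min(2, len(self.references_))
        return (hits[0] if len(hits) == required else None), d1, d2

    def gate(self, fp: np.ndarray) -> tuple[str | None, float | None, float | None]:
        """Apply the similarity gate to one fingerprint.

        Returns ``(pathway, d_s1, d_s2)`` with ``pathway`` one of
        ``'gate_S1'``/``'gate_S2'`` (sweet by similarity) or ``None``
        (pass to consensus).
        """
        return self._gate_outcome(np.asarray(fp))

    # -------------------------------------------------------------- predict

    def predict(
        self,
        fingerprints: FingerprintMatrix,
        descriptors: DescriptorTable | None = None,
    ) -> list[ExpertPrediction]:
        """Run the full workflow over a batch of molecules.

        A consensus-path molecule with no descriptor row errors
        individually (pathway ``'error'``); the batch continues.
        """
        desc_index = (
            {mol_id: i for i, mol_id in enumerate(descriptors.ids)}
            if descriptors is not None
            else {}
        )
        out: list[ExpertPrediction] = []
        for i, mol_id in enumerate(fingerprints.ids):
            fp = fingerprints.bits[i]
            pathway, d1, d2 = self._gate_outcome(fp)
            if pathway is not None:
                out.append(
                    ExpertPrediction(mol_id, SWEET, pathway, d1, d2, in_ad=True)
                )
                continue
            if mol_id not in desc_index:
                out.append(
                    ExpertPrediction(
                        mol_id, NOT_ASSIGNED, "error", d1, d2,
                        error="descriptor row missing",
                    )
                )
                continue
            x = descriptors.values[[desc_index[mol_id]]]
            n3_class = str(self.n3_.predict(x)[0])
            proba = self.n3_.predict_proba(x)[0]
            sweet_pos = int(np.where(self.n3_.classes_ == SWEET)[0][0])
            pls_class = str(self.plsda_.predict(x)[0])
            final = consensus_predict(n3_class, pls_class)
            h = float(self.plsda_.leverage(x)[0])
            h_star = self.plsda_.leverage_threshold_
            lev_ok = h <= h_star
            sim_ok = bool(self.n3_.average_similarity(x)[0] >= self.similarity_cutoff_)
            in_ad = (lev_ok and sim_ok) if self.ad_rule == "both" else (lev_ok or sim_ok)
            out.append(
                ExpertPrediction(
                    mol_id, final, CONSENSUS, d1, d2,
                    n3_class=n3_class,
                    n3_score_sweet=float(proba[sweet_pos]),
                    plsda_class=pls_class,
                    in_ad=in_ad, leverage=h, h_star=h_star,
                    leverage_ok=lev_ok, similarity_ok=sim_ok,
                )
            )
        return out

    def assess_ad(self, fp: np.ndarray, descriptor_row=None) -> dict:
        """Two-branch applicability-domain verdict for one molecule."""
        pathway, d1, d2 = self._gate_outcome(np.asarray(fp))
        if pathway is not None:
            return {"in_ad": True, "pathway": pathway, "d_s1": d1, "d_s2": d2}
        if descriptor_row is None:
            raise ValueError("descriptor row required for consensus-path AD assessment")
        x = np.atleast_2d(np.asarray(descriptor_row, dtype=float))
        h = float(self.plsda_.leverage(x)[0])
        h_star = self.plsda_.leverage_threshold_
        lev_ok = h <= h_star
        sim = float(self.n3_.average_similarity(x)[0])
        sim_ok = sim >= self.similarity_cutoff_
        in_ad = (lev_ok and sim_ok) if self.ad_rule == "both" else (lev_ok or sim_ok)
        return {
            "in_ad": in_ad, "pathway": CONSENSUS,
            "leverage": h, "h_star": h_star, "leverage_ok": lev_ok,
            "average_similarity": sim, "similarity_cutoff": self.similarity_cutoff_,
            "similarity_ok": sim_ok,
        }

    # ------------------------------------------------------------- reports

    def evaluate(
        self,
        fingerprints: FingerprintMatrix,
        descriptors: DescriptorTable,
        y,
        context: str = "fitting",
    ) -> ValidationReport:
        predictions = self.predict(fingerprints, descriptors)
        y_pred = [p.class_label for p in predictions]
        return class_metrics(y, y_pred, context=context)

    # -------------------------------------------------------- serialization

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {
            "fingerprint_params": asdict(self.fingerprint_params),
            "s1_threshold": self.s1_threshold,
            "s2_threshold": self.s2_threshold,
            "gate_rule": self.gate_rule,
            "alpha": self.alpha_,
            "n_lv": self.n_lv_,
            "ad_percentile": self.ad_percentile,
            "ad_rule": self.ad_rule,
            "similarity_cutoff": self.similarity_cutoff_,
            "references": [
                {"name": r.name, "threshold": r.threshold, "member_ids": r.member_fps.ids}
                for r in self.references_
            ],
            "descriptor_names": self.descriptor_names_,
            "version": __import__("sweetgate").__version__,
        }
        (directory / "config.json").write_text(json.dumps(config, indent=2))
        for r in self.references_:
            r.member_fps.to_csv(directory / f"reference_{r.name}.csv")
        n3_payload = {
            "alpha": self.n3_.alpha,
            "X_min": self.n3_.scaler_.min_.tolist(),
            "X_max": self.n3_.scaler_.max_.tolist(),
            "X_scaled": self.n3_.X_train_.tolist(),
            "y": list(self.n3_.y_train_),
        }
        (directory / "n3.json").write_text(json.dumps(n3_payload))
        pls = self.plsda_
        pls_payload = {
            "n_lv": pls.n_lv,
            "classes": list(pls.classes_),
            "mean": pls.scaler_.mean_.tolist(),
            "scale": pls.scaler_.scale_.tolist(),
            "y_mean": pls.y_mean_.tolist(),
            "coef": pls.coef_.tolist(),
            "rotations": pls.x_rotations_.tolist(),
            "score_gram_inv": pls._score_gram_inv_.tolist(),
            "n_train": pls.n_train_,
        }
        (directory / "plsda.json").write_text(json.dumps(pls_payload))

    @classmethod
    def load(cls, directory: str | Path) -> "SweetTasteExpertSystem":
        directory = Path(directory)
        config = json.loads((directory / "config.json").read_text())
        system = cls(
            fingerprint_params=FingerprintParams(**config["fingerprint_params"]),
            s1_threshold=config["s1_threshold"],
            s2_threshold=config["s2_threshold"],
            gate_rule=config["gate_rule"],
            alpha=config["alpha"],
            n_lv=config["n_lv"],
            ad_percentile=config["ad_percentile"],
            ad_rule=config["ad_rule"],
        )
        system.references_ = []
        for ref in config["references"]:
            fps = FingerprintMatrix.from_csv(directory / f"reference_{ref['name']}.csv")
            system.references_.append(
                ClusterReference(ref["name"], fps, ref["threshold"])
            )
        n3_payload = json.loads((directory / "n3.json").read_text())
        n3 = N3Classifier(alpha=n3_payload["alpha"])
        n3.classes_ = np.unique(np.asarray(n3_payload["y"], dtype=object))
        from .preprocessing import RangeScaler

        scaler = RangeScaler()
        scaler.min_ = np.asarray(n3_payload["X_min"])
        scaler.max_ = np.asarray(n3_payload["X_max"])
        scaler.n_features_in_ = scaler.min_.size
        n3.scaler_ = scaler
        n3.X_train_ = np.asarray(n3_payload["X_scaled"])
        n3.y_train_ = np.asarray(n3_payload["y"], dtype=object)
        n3.n_features_in_ = scaler.n_features_in_
        system.n3_ = n3
        pls_payload = json.loads((directory / "plsda.json").read_text())
        pls = PLSDAClassifier(n_lv=pls_payload["n_lv"])
        pls.classes_ = np.asarray(pls_payload["classes"], dtype=object)
        from .preprocessing import Autoscaler

        ascaler = Autoscaler()
        ascaler.mean_ = np.asarray(pls_payload["mean"])
        ascaler.scale_ = np.asarray(pls_payload["scale"])
        ascaler.n_features_in_ = ascaler.mean_.size
        pls.scaler_ = ascaler
        pls.y_mean_ = np.asarray(pls_payload["y_mean"])
        pls.coef_ = np.asarray(pls_payload["coef"])
        pls.x_rotations_ = np.asarray(pls_payload["rotations"])
        pls._score_gram_inv_ = np.asarray(pls_payload["score_gram_inv"])
        pls.n_train_ = pls_payload["n_train"]
        pls.n_features_in_ = ascaler.n_features_in_
        pls.x_scores_ = np.zeros((pls.n_train_, pls.n_lv))  # marker for check_is_fitted
        system.plsda_ = pls
        system.alpha_, system.n_lv_ = n3.alpha, pls.n_lv
        system.similarity_cutoff_ = config["similarity_cutoff"]
        system.descriptor_names_ = config["descriptor_names"]
        return system


def monte_carlo_expert(
    fingerprints: FingerprintMatrix,
    descriptors: DescriptorTable,
    y,
    system: SweetTasteExpertSystem,
    n_iter: int = 1000,
    eval_fraction: float = 0.2,
    seed: int = 0,
    refit: str = "classifiers",
) -> ValidationReport:
    """Monte Carlo (leave-many-out) validation of a fitted expert system.

    Each iteration draws a stratified 80/20 split, refits on the 80% and
    predicts the 20%; metrics are computed once on the cumulative pool.
    With ``refit='classifiers'`` (default) the cluster references and gate
    thresholds stay fixed from the initial fit and only the consensus
    classifiers are retrained; ``refit='full'`` rediscovers the clusters
    each iteration.
    """
    if refit not in ("classifiers", "full"):
        raise ValueError("refit must be 'classifiers' or 'full'")
    y = np.asarray(y, dtype=object)
    fixed_refs = list(getattr(system, "references_", []))
    params = dict(
        s1_threshold=system.s1_threshold,
        s2_threshold=system.s2_threshold,
        gate_rule=system.gate_rule,
        alpha=getattr(system, "alpha_", system.alpha),
        n_lv=getattr(system, "n_lv_", system.n_lv),
        ad_percentile=system.ad_percentile,
        ad_rule=system.ad_rule,
        cv_groups=system.cv_groups,
    )

    def evaluate_split(train_idx, eval_idx, fit_seed):
        sub = SweetTasteExpertSystem(
            fingerprint_params=system.fingerprint_params,
            cluster_seed=fit_seed, **params,
        )
        refs = fixed_refs if refit == "classifiers" else None
        train_fps = fingerprints.subset(train_idx)
        train_desc = descriptors.subset_rows(train_idx)
        sub.fit(train_fps, train_desc, y[train_idx], cluster_references=refs)
        preds = sub.predict(fingerprints.subset(eval_idx), descriptors.subset_rows(eval_idx))
        return y[eval_idx], [p.class_label for p in preds]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        return monte_carlo_validate(
            y, evaluate_split, n_iter=n_iter, eval_fraction=eval_fraction, seed=seed
        )
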