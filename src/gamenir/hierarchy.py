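"""Multilevel hierarchical classification cascade.

A tree of PLS-DA nodes: the root discriminates species; under each species
label sit two sibling nodes, one separating fresh from frozen-thawed meat
and one separating the muscle groups (forequarter vs hindquarter for the
ungulates, the two individual muscles for ostrich).  Every node carries its
own pre-treatment pipeline and LV count and re-applies that pipeline to the
raw (averaged, trimmed) spectra, since sibling nodes use incompatible
pre-treatments.

Semantics: nodes are TRAINED on the calibration subsets selected by their
ancestors' true labels, but EVALUATED on the samples ROUTED to them by the
fitted cascade (so a sample misrouted at the root is judged by the wrong
species' sub-models, and the trace records where it diverged).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectraSet
from .plsda import PLSDAClassifier
from .preprocess import PreprocessPipeline, snv_detrend, sg_derivative, snv_detrend_sg


@dataclasses.dataclass
class HierarchyNode:
    """One cascade node: a label field to predict, its pipeline and LV count.

    ``children`` maps a predicted label of THIS node to the list of nodes a
    sample routed under that label visits next (siblings all see the same
    routed samples).
    """

    name: str
    target_field: str
    pipeline: PreprocessPipeline
    n_lv: int
    children: dict = dataclasses.field(default_factory=dict)
    model: PLSDAClassifier | None = None

    def walk(self):
        yield self
        for nodes in self.children.values():
            for child in nodes:
                yield from child.walk()


def default_tree() -> HierarchyNode:
    """The bundled cascade: per-node pre-treatments and LV counts from the
    study's validated hierarchical model (species root, then per-species
    fresh/frozen-thawed and muscle-group nodes)."""
    zebra = [
        HierarchyNode("zebra/treatment", "treatment", sg_derivative(1, 5), 5),
        HierarchyNode("zebra/muscle_group", "muscle_group", snv_detrend_sg(2, 9), 6),
    ]
    springbok = [
        HierarchyNode("springbok/treatment", "treatment", snv_detrend(), 2),
        HierarchyNode("springbok/muscle_group", "muscle_group", snv_detrend_sg(2, 7), 5),
    ]
    ostrich = [
        HierarchyNode("ostrich/treatment", "treatment", sg_derivative(1, 5), 3),
        # BD and FF are their own muscle groups, so targeting muscle_group
        # here is the same discrimination as muscle while keeping the joint
        # (species, treatment, muscle_group) tuple total for every sample.
        HierarchyNode("ostrich/muscle", "muscle_group", snv_detrend(), 5),
    ]
    return HierarchyNode(
        "species", "species", sg_derivative(1, 7), 8,
        children={"zebra": zebra, "springbok": springbok, "ostrich": ostrich},
    )


class HierarchicalClassifier:
    """Fit/predict/evaluate interface over a :class:`HierarchyNode` tree."""

    def __init__(self, root: HierarchyNode | None = None):
        self.root = root if root is not None else default_tree()

    # -- fitting ------------------------------------------------------------

    def fit(self, cal: SpectraSet) -> "HierarchicalClassifier":
        if "muscle_group" in self._target_fields() and "muscle_group" not in cal.meta:
            cal = cal.add_muscle_group()
        self._fit_node(self.root, cal, path="root")
        return self

    def _target_fields(self):
        return {node.target_field for node in self.root.walk()}

    def _fit_node(self, node: HierarchyNode, subset: SpectraSet, path: str):
        if subset.n_samples == 0:
            raise ValueError(f"empty training subset at node {path}/{node.name}")
        if node.target_field not in subset.meta:
            raise ValueError(f"metadata lacks field {node.target_field!r} "
                             f"needed by node {node.name}")
        X = node.pipeline.transform(subset.X, wavelengths=subset.wavelengths)
        y = subset.meta[node.target_field].to_numpy()
        n_lv = min(node.n_lv, subset.n_samples - 1, X.shape[1])
        node.model = PLSDAClassifier(n_components=n_lv).fit(X, y)
        for label, children in node.children.items():
            mask = subset.meta[node.target_field].to_numpy() == label
            if not mask.any():
                raise ValueError(f"no calibration samples with "
                                 f"{node.target_field}={label!r} under {path}")
            child_subset = subset.select(mask)
            for child in children:
                self._fit_node(child, child_subset, path=f"{path}/{label}")

    # -- prediction ---------------------------------------------------------

    def predict(self, dataset: SpectraSet) -> pd.DataFrame:
        """Route every sample through the cascade.

        Returns one row per sample with a predicted value per target field
        plus ``route``, the sequence of node names visited.
        """
        n = dataset.n_samples
        out = {field: np.array([None] * n, dtype=object) for field in self._target_fields()}
        routes = [[] for _ in range(n)]
        self._predict_node(self.root, dataset, np.arange(n), out, routes)
        frame = pd.DataFrame(out, index=dataset.meta.index)
        frame["route"] = ["/".join(r) for r in routes]
        return frame

    def _predict_node(self, node, dataset, indices, out, routes):
        if node.model is None:
            raise RuntimeError(f"node {node.name} is not fitted")
        subset = dataset.select(indices)
        X = node.pipeline.transform(subset.X, wavelengths=subset.wavelengths)
        pred = node.model.predict(X)
        for local, global_i in enumerate(indices):
            out[node.target_field][global_i] = pred[local]
            routes[global_i].append(node.name)
        for label, children in node.children.items():
            routed = indices[pred == label]
            if routed.size == 0:
                continue
            for child in children:
                self._predict_node(child, dataset, routed, out, routes)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, val: SpectraSet) -> "HierarchyReport":
        """Routed-evaluation report per node and class, plus joint accuracy."""
        if "muscle_group" in self._target_fields() and "muscle_group" not in val.meta:
            val = val.add_muscle_group()
        pred = self.predict(val)
        rows = []
        self._evaluate_node(self.root, val, pred, np.arange(val.n_samples), rows)
        fields = sorted(self._target_fields())
        joint_ok = np.ones(val.n_samples, dtype=bool)
        for field in fields:
            joint_ok &= pred[field].to_numpy() == val.meta[field].to_numpy()
        return HierarchyReport(pd.DataFrame(rows), fields,
                               n_total=val.n_samples,
                               n_joint_correct=int(joint_ok.sum()),
                               predictions=pred)

    def _evaluate_node(self, node, val, pred, indices, rows):
        y_true = val.meta[node.target_field].to_numpy()[indices]
        y_pred = pred[node.target_field].to_numpy()[indices]
        def row(cls, mask):
            nT = int(mask.sum())
            nP = int((y_pred[mask] == y_true[mask]).sum())
            return dict(node=node.name, pre_treatment=node.pipeline.label,
                        n_lv=node.n_lv, target=node.target_field,
                        cls=cls, nT=nT, nP=nP,
                        accuracy_pct=100.0 * nP / nT if nT else np.nan)
        rows.append(row("overall", np.ones(indices.size, dtype=bool)))
        for cls in node.model.classes_:
            rows.append(row(cls, y_true == cls))
        for label, children in node.children.items():
            routed = indices[y_pred == label]
            if routed.size == 0:
                continue
            for child in children:
                self._evaluate_node(child, val, pred, routed, rows)


@dataclasses.dataclass
class HierarchyReport:
    """Per-node routed accuracies plus the joint-tuple accuracy."""

    table: pd.DataFrame
    fields: list
    n_total: int
    n_joint_correct: int
    predictions: pd.DataFrame

    @property
    def joint_accuracy_pct(self) -> float:
        return 100.0 * self.n_joint_correct / self.n_total

    def node_accuracy(self, node: str, cls="overall") -> float:
        sel = self.table[(self.table["node"] == node) & (self.table["cls"] == cls)]
        if sel.empty:
            raise KeyError(f"no report row for node {node!r}, class {cls!r}")
        return float(sel["accuracy_pct"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config serialisation (nested YAML)
# ---------------------------------------------------------------------------

def node_to_dict(node: HierarchyNode) -> dict:
    return {
        "name": node.name,
        "target_field": node.target_field,
        "pipeline": node.pipeline.to_config(),
        "n_lv": node.n_lv,
        "children": {label: [node_to_dict(c) for c in nodes]
                     for label, nodes in node.children.items()},
    }


def node_from_dict(d: dict) -> HierarchyNode:
    return HierarchyNode(
        name=d["name"],
        target_field=d["target_field"],
        pipeline=PreprocessPipeline.from_config(d["pipeline"]),
        n_lv=int(d["n_lv"]),
        children={label: [node_from_dict(c) for c in nodes]
                  for label, nodes in d.get("children", {}).items()},
    )


def save_tree(node: HierarchyNode, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(node_to_dict(node), fh, sort_keys=False)


def load_tree(path) -> HierarchyNode:
    with open(path) as fh:
        return node_from_dict(yaml.safe_load(fh))
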