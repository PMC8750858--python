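"""Factor hierarchies: target -> criteria -> sub-criteria -> leaf factors.

The default hierarchy groups the modelled risk factors of a schizophrenia
follow-up cohort under three main criteria — demography, treatment and
disease course — with each leaf bound to a cohort-table variable.  Every
internal node carries a pairwise comparison matrix (or a weight vector it
was built from) whose normalized principal eigenvector gives the local
weights of its children; leaf *global* weights are the product of local
weights along the path from the root and sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ahp import (
    AHPError,
    ConsistencyReport,
    PairwiseMatrix,
    consistency_index,
    consistency_ratio,
    consistency_report,
    matrix_from_weights,
    principal_weights,
    random_index,
    repair_matrix,
)

__all__ = ["Node", "FactorHierarchy", "default_hierarchy", "hierarchy_from_weights"]


@dataclass
class Node:
    """A hierarchy node; leaves bind to a dataset variable."""

    name: str
    children: list["Node"] = field(default_factory=list)
    variable: str | None = None
    matrix: PairwiseMatrix | None = None
    local_weights: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class FactorHierarchy:
    """A rooted factor tree with per-node comparison matrices and weights."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[int] = set()

        def walk(node: Node) -> None:
            if id(node) in seen:
                raise AHPError(f"node {node.name!r} has more than one parent")
            seen.add(id(node))
            if node.is_leaf and node.variable is None:
                node.variable = node.name
            if len(node.children) == 1 and node.local_weights is None:
                node.local_weights = np.ones(1)  # single child: weight 1, no matrix
            for c in node.children:
                walk(c)

        walk(self.root)
        names = [leaf.name for leaf in self.leaves()]
        if len(set(names)) != len(names):
            raise AHPError("leaf names must be unique")

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    # -- weight resolution -------------------------------------------------

    def solve_weights(self, repair: bool = True, max_iter: int = 50) -> None:
        """Fill each internal node's local weights from its matrix.

        Matrices failing the CR < 0.10 test are repaired first (or the call
        fails if ``repair=False``).
        """
        for node in self.internal_nodes():
            if len(node.children) == 1:
                node.local_weights = np.ones(1)
                continue
            if node.matrix is None:
                if node.local_weights is not None:
                    continue
                raise AHPError(f"internal node {node.name!r} has neither matrix nor weights")
            A = node.matrix
            if not consistency_report(A).acceptable:
                if not repair:
                    raise AHPError(f"matrix at {node.name!r} fails the consistency test")
                A = repair_matrix(A, max_iter=max_iter)
                node.matrix = A
            node.local_weights, _ = principal_weights(A)

    def synthesize_global_weights(self) -> tuple[dict[str, float], ConsistencyReport]:
        """Leaf global weights plus the hierarchy-wide combination consistency.

        Global weight of a leaf = product of local weights on its root path.
        The combination test aggregates Σ(node global weight · CI_node) over
        Σ(node global weight · RI_node) across all internal nodes, with the
        usual < 0.10 acceptance.
        """
        globals_: dict[str, float] = {}
        num = den = 0.0

        def walk(node: Node, g: float) -> None:
            nonlocal num, den
            if node.is_leaf:
                globals_[node.name] = globals_.get(node.name, 0.0) + g
                return
            if node.local_weights is None:
                raise AHPError(f"internal node {node.name!r} has no local weights; call solve_weights")
            w = np.asarray(node.local_weights, dtype=float)
            if len(w) != len(node.children):
                raise AHPError(f"weight length mismatch at {node.name!r}")
            if node.matrix is not None:
                rep = consistency_report(node.matrix)
                if not rep.acceptable:
                    raise AHPError(f"matrix at {node.name!r} is inconsistent and unrepaired")
                num += g * rep.ci
                den += g * rep.ri
            for c, wc in zip(node.children, w):
                walk(c, g * float(wc))

        walk(self.root, 1.0)
        total = sum(globals_.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise AHPError(f"global weights sum to {total}, expected 1")
        cr = num / den if den > 0 else 0.0
        report = ConsistencyReport(
            lambda_max=float("nan"), ci=num, ri=den, cr=cr, acceptable=cr < 0.10
        )
        return globals_, report

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def conv(node: Node) -> dict:
            d: dict = {"name": node.name}
            if node.is_leaf:
                if node.variable != node.name:
                    d["variable"] = node.variable
                return d
            d["children"] = [conv(c) for c in node.children]
            if node.matrix is not None:
                d["matrix"] = node.matrix.values.tolist()
            elif node.local_weights is not None:
                d["weights"] = list(map(float, node.local_weights))
            return d

        return conv(self.root)

    @classmethod
    def from_dict(cls, d: dict) -> "FactorHierarchy":
        def conv(d: dict) -> Node:
            node = Node(name=d["name"], variable=d.get("variable"))
            for c in d.get("children", []):
                node.children.append(conv(c))
            if "matrix" in d:
                node.matrix = PairwiseMatrix(d["matrix"])
            elif "weights" in d:
                w = np.asarray(d["weights"], dtype=float)
                node.local_weights = w / w.sum()
            return node

        return cls(conv(d))

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "FactorHierarchy":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(d)


#: Default criteria tree: three main criteria over the cohort variables.
_DEFAULT_TREE: dict[str, dict[str, str]] = {
    "demography": {
        "region": "region",
        "age": "age",
        "gender": "gender",
        "education": "education",
        "disability_grade": "disability_rating",
        "social_support": "social_function",
        "economic_status": "economic_status",
    },
    "treatment": {
        "adverse_reaction": "adverse_reactions_times",
        "compliance": "compliance",
        "treatment": "auxiliary_drug_combination",
        "drug_combination": "drug_combination",
    },
    "disease_course": {
        "hospitalizations": "hospitalization_times",
        "risk_events": "referral_times",
        "annual_policy": "policy_period",
        "duration": "course_years",
    },
}


def default_hierarchy() -> FactorHierarchy:
    """The three-criteria hierarchy (demography / treatment / disease course)."""
    root = Node(name="risk_score")
    for crit, leaves in _DEFAULT_TREE.items():
        c = Node(name=crit)
        for leaf, var in leaves.items():
            c.children.append(Node(name=leaf, variable=var))
        root.children.append(c)
    return FactorHierarchy(root)


def hierarchy_from_weights(
    h: FactorHierarchy,
    leaf_weights: dict[str, float],
    quantize: bool = True,
    repair: bool = True,
) -> FactorHierarchy:
    """Seed every comparison matrix of ``h`` from per-leaf weight magnitudes.

    Each internal node's children are weighted by the summed leaf weights
    beneath them; the node's matrix is built with ``matrix_from_weights``
    (optionally Saaty-quantized), repaired if needed, and its local weights
    re-derived from the principal eigenvector.  Returns ``h`` mutated.
    """

    def subtree_weight(node: Node) -> float:
        if node.is_leaf:
            if node.variable not in leaf_weights and node.name not in leaf_weights:
                raise AHPError(f"no seed weight for leaf {node.name!r} ({node.variable!r})")
            return float(leaf_weights.get(node.variable, leaf_weights.get(node.name, 0.0)))
        return sum(subtree_weight(c) for c in node.children)

    for node in h.internal_nodes():
        if len(node.children) == 1:
            node.local_weights = np.ones(1)
            continue
        w = np.array([subtree_weight(c) for c in node.children], dtype=float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        node.matrix = matrix_from_weights(w / w.sum(), quantize=quantize)
    h.solve_weights(repair=repair)
    return h
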