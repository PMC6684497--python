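"""Multinomial processing tree (MPT) model structure and likelihood.

An MPT reparametrizes the category probabilities of one or more independent
multinomial distributions ("subtrees" or category systems) as sums of branch
probabilities, where each branch probability is a product of latent process
probabilities ``theta_p`` and their complements ``1 - theta_p``.

The model structure is held in :class:`MptModelSpec`; per-participant count
data in :class:`CountTable`.  Models are read from EQN-style text files, the
community convention for MPT software: one line per branch, giving a subtree
label, a category label, and a ``*``-separated product of factors ``p`` or
``(1-p)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

__all__ = [
    "MptModelSpec",
    "CountTable",
    "parse_eqn",
    "read_eqn",
    "branch_probability",
    "category_probabilities",
    "log_likelihood",
    "read_counts_csv",
    "write_counts_csv",
]


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: factors are (parameter index, complement flag)."""

    factors: tuple[tuple[int, bool], ...]

    def exponents(self, P: int) -> tuple[np.ndarray, np.ndarray]:
        """Exponent vectors (v, w) of theta_p and (1 - theta_p) for this branch."""
        v = np.zeros(P, dtype=np.int64)
        w = np.zeros(P, dtype=np.int64)
        for p, comp in self.factors:
            if comp:
                w[p] += 1
            else:
                v[p] += 1
        return v, w


@dataclass
class MptModelSpec:
    """Structure of an MPT model.

    Attributes
    ----------
    name : str
        Model label.
    parameters : list of str
        Ordered free parameter names (length ``P``).
    subtree_labels : list of str
        File labels of the ``K`` subtrees, in first-appearance order.
    category_labels : list of list of str
        Per subtree, the ``L_k`` category labels in first-appearance order.
    branches : list of list of list of Branch
        ``branches[k][l]`` is the list of ``M_kl`` branches ending in
        category ``l`` of subtree ``k``.
    """

    name: str
    parameters: list[str]
    subtree_labels: list[str]
    category_labels: list[list[str]]
    branches: list[list[list[Branch]]]
    constraints: dict[str, str] = field(default_factory=dict)

    # ------------------------------------------------------------------ sizes
    @property
    def P(self) -> int:
        return len(self.parameters)

    @property
    def K(self) -> int:
        return len(self.subtree_labels)

    @property
    def L(self) -> list[int]:
        """Number of categories per subtree."""
        return [len(c) for c in self.category_labels]

    @property
    def n_categories(self) -> int:
        return sum(self.L)

    def validate(self) -> None:
        P = self.P
        if P < 1:
            raise ValueError("model declares no parameters")
        for k, cats in enumerate(self.branches):
            if len(cats) < 1:
                raise ValueError(f"subtree {self.subtree_labels[k]!r} has no categories")
            for l, brs in enumerate(cats):
                if len(brs) < 1:
                    raise ValueError(
                        f"category {self.category_labels[k][l]!r} of subtree "
                        f"{self.subtree_labels[k]!r} has no branches"
                    )
                for br in brs:
                    for p, _ in br.factors:
                        if not 0 <= p < P:
                            raise ValueError("branch factor references undeclared parameter")

    # --------------------------------------------------------- flat structure
    def flat_structure(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Branch exponent matrices in a flat, category-sorted layout.

        Returns ``(V, W, offsets, cat_offsets)`` where ``V`` and ``W`` are
        ``(B, P)`` exponent matrices over all branches ordered by flattened
        category index, ``offsets[j]`` is the first branch row of flattened
        category ``j`` (length ``n_categories``), and ``cat_offsets[k]`` the
        first flattened category of subtree ``k`` (length ``K + 1``).
        """
        V_rows, W_rows, offsets = [], [], []
        cat_offsets = [0]
        b = 0
        for k in range(self.K):
            for brs in self.branches[k]:
                offsets.append(b)
                for br in brs:
                    v, w = br.exponents(self.P)
                    V_rows.append(v)
                    W_rows.append(w)
                    b += 1
            cat_offsets.append(cat_offsets[-1] + len(self.branches[k]))
        V = np.asarray(V_rows, dtype=float)
        W = np.asarray(W_rows, dtype=float)
        return V, W, np.asarray(offsets), np.asarray(cat_offsets)

    def with_parameter_order(self, order: list[str]) -> "MptModelSpec":
        """Return an equivalent spec with parameters listed in ``order``.

        Useful to align two structurally different models over the same
        parameter set (e.g. for non-nested comparison), where first-appearance
        indexing would otherwise order them differently.
        """
        if sorted(order) != sorted(self.parameters):
            raise ValueError("order must be a permutation of the declared parameters")
        remap = {old: order.index(name) for old, name in enumerate(self.parameters)}
        new_branches = [
            [
                [Branch(tuple((remap[p], comp) for p, comp in br.factors)) for br in brs]
                for brs in cats
            ]
            for cats in self.branches
        ]
        return MptModelSpec(
            name=self.name,
            parameters=list(order),
            subtree_labels=list(self.subtree_labels),
            category_labels=[list(c) for c in self.category_labels],
            branches=new_branches,
            constraints=dict(self.constraints),
        )

    def apply_constraints(self, constraints: dict[str, str]) -> "MptModelSpec":
        """Return a spec with equality constraints applied (e.g. ``{"a": "u"}``).

        Constrained parameters are removed from the free-parameter list and
        every branch factor that references one is redirected to its target,
        so the constrained model has fewer free dimensions.
        """
        for src, dst in constraints.items():
            if src not in self.parameters or dst not in self.parameters:
                raise ValueError(f"constraint {src}={dst} references unknown parameter")
            if src == dst:
                raise ValueError(f"constraint {src}={dst} is vacuous")
        resolved = {}
        for src, dst in constraints.items():
            seen = {src}
            while dst in constraints:
                dst = constraints[dst]
                if dst in seen:
                    raise ValueError("cyclic equality constraints")
                seen.add(dst)
            resolved[src] = dst
        keep = [p for p in self.parameters if p not in resolved]
        new_index = {name: i for i, name in enumerate(keep)}
        remap = {
            old: new_index[resolved.get(name, name)]
            for old, name in enumerate(self.parameters)
        }
        new_branches = [
            [
                [
                    Branch(tuple((remap[p], comp) for p, comp in br.factors))
                    for br in brs
                ]
                for brs in cats
            ]
            for cats in self.branches
        ]
        return MptModelSpec(
            name=self.name,
            parameters=keep,
            subtree_labels=list(self.subtree_labels),
            category_labels=[list(c) for c in self.category_labels],
            branches=new_branches,
            constraints={**self.constraints, **constraints},
        )


@dataclass
class CountTable:
    """Per-participant, per-condition category counts for an MPT.

    ``counts`` has shape ``(I, n_conditions, n_categories)`` with categories
    flattened across subtrees in spec order; row sums within each subtree
    block equal the item total ``J_k`` of that subtree.
    """

    counts: np.ndarray
    J: np.ndarray
    cat_offsets: np.ndarray
    subtree_labels: list[str]
    category_labels: list[list[str]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim == 2:
            self.counts = self.counts[:, None, :]
        self.J = np.asarray(self.J, dtype=np.int64)
        self.cat_offsets = np.asarray(self.cat_offsets, dtype=np.int64)
        if self.counts.shape[0] < 1:
            raise ValueError("need at least one participant")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        for k in range(len(self.J)):
            block = self.counts[:, :, self.cat_offsets[k] : self.cat_offsets[k + 1]]
            if not np.all(block.sum(axis=-1) == self.J[k]):
                raise ValueError(
                    f"counts in subtree {self.subtree_labels[k]!r} do not sum to J={self.J[k]}"
                )

    @property
    def I(self) -> int:
        return self.counts.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_spec(cls, spec: MptModelSpec, counts: np.ndarray, J) -> "CountTable":
        _, _, _, cat_offsets = spec.flat_structure()
        return cls(
            counts=counts,
            J=J,
            cat_offsets=cat_offsets,
            subtree_labels=list(spec.subtree_labels),
            category_labels=[list(c) for c in spec.category_labels],
        )


# ---------------------------------------------------------------------------
# EQN parsing
# ---------------------------------------------------------------------------

_FACTOR_RE = re.compile(r"^(?:\(\s*1\s*-\s*([A-Za-z_]\w*)\s*\)|([A-Za-z_]\w*)|1)$")


def parse_eqn(text: str, name: str = "mpt") -> MptModelSpec:
    """Parse an EQN-dialect model description into an :class:`MptModelSpec`.

    Each non-comment line reads ``subtree category branch`` with the branch a
    ``*``-separated product of factors ``p`` or ``(1-p)``; fields may also be
    separated by semicolons.  ``#`` starts a comment; an optional leading line
    holding a single integer (the traditional branch count) is ignored.
    Repeated (subtree, category) lines accumulate as additional branches.
    Subtrees, categories, and parameters are indexed by first appearance.
    """
    lines = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            lines.append(line)
    if lines and re.fullmatch(r"-?\d+", lines[0]):
        lines = lines[1:]
    if not lines:
        raise ValueError("empty EQN input")

    parameters: list[str] = []
    param_index: dict[str, int] = {}
    subtree_labels: list[str] = []
    category_labels: list[list[str]] = []
    branches: list[list[list[Branch]]] = []

    for line in lines:
        parts = [t for t in re.split(r"[;\s]+", line) if t]
        if len(parts) != 3:
            raise ValueError(f"malformed EQN line (expected 3 fields): {line!r}")
        tree_lab, cat_lab, expr = parts
        factors = []
        for tok in expr.split("*"):
            tok = tok.strip()
            m = _FACTOR_RE.match(tok)
            if m is None:
                raise ValueError(f"malformed factor token {tok!r} in line {line!r}")
            pname = m.group(1) or m.group(2)
            if pname is None:  # literal "1": empty factor
                continue
            if pname not in param_index:
                param_index[pname] = len(parameters)
                parameters.append(pname)
            factors.append((param_index[pname], m.group(1) is not None))
        if tree_lab not in subtree_labels:
            subtree_labels.append(tree_lab)
            category_labels.append([])
            branches.append([])
        k = subtree_labels.index(tree_lab)
        if cat_lab not in category_labels[k]:
            category_labels[k].append(cat_lab)
            branches[k].append([])
        l = category_labels[k].index(cat_lab)
        branches[k][l].append(Branch(tuple(factors)))

    spec = MptModelSpec(
        name=name,
        parameters=parameters,
        subtree_labels=subtree_labels,
        category_labels=category_labels,
        branches=branches,
    )
    spec.validate()
    return spec


def read_eqn(path, name: str | None = None) -> MptModelSpec:
    """Read an EQN model file from disk."""
    with open(path) as fh:
        text = fh.read()
    return parse_eqn(text, name=name or str(path))


def write_eqn(spec: MptModelSpec, path) -> None:
    """Write a spec back out in the EQN dialect consumed by :func:`parse_eqn`."""
    lines = []
    for k in range(spec.K):
        for l, brs in enumerate(spec.branches[k]):
            for br in brs:
                toks = [
                    f"(1-{spec.parameters[p]})" if comp else spec.parameters[p]
                    for p, comp in br.factors
                ] or ["1"]
                lines.append(
                    f"{spec.subtree_labels[k]} {spec.category_labels[k][l]} "
                    + "*".join(toks)
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Probabilities and likelihood
# ---------------------------------------------------------------------------


def _check_theta(spec: MptModelSpec, theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.P,):
        raise ValueError(f"theta must have length P={spec.P}, got shape {theta.shape}")
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta components must lie in [0, 1]")
    return theta


def branch_probability(spec: MptModelSpec, k: int, l: int, m: int, theta) -> float:
    """Probability of branch ``m`` of category ``l`` in subtree ``k``.

    The branch probability is the product of the process probabilities
    encountered on the root-to-leaf path:
    ``prod_p theta_p**v_p * (1 - theta_p)**w_p``.
    """
    theta = _check_theta(spec, theta)
    try:
        br = spec.branches[k][l][m]
    except IndexError:
        raise KeyError(f"unknown branch reference (k={k}, l={l}, m={m})") from None
    v, w = br.exponents(spec.P)
    # 0**0 == 1 under np.power, so boundary thetas are handled exactly
    return float(np.prod(theta**v * (1.0 - theta) ** w))


def category_probabilities(spec: MptModelSpec, theta) -> list[np.ndarray]:
    """Per-subtree category probability vectors at ``theta``.

    Each category probability is the sum of its branch probabilities; within
    each subtree the vector sums to 1 for interior ``theta``.
    """
    theta = _check_theta(spec, theta)
    out = []
    for k in range(spec.K):
        probs = np.array(
            [
                sum(
                    np.prod(theta ** br.exponents(spec.P)[0] * (1.0 - theta) ** br.exponents(spec.P)[1])
                    for br in brs
                )
                for brs in spec.branches[k]
            ]
        )
        out.append(probs)
    return out


def log_likelihood(spec: MptModelSpec, counts_row, theta, J=None) -> float:
    """Product-multinomial log-likelihood of one participant's counts.

    ``counts_row`` is the flattened category count vector (spec order).  The
    value includes the multinomial coefficients (computed via log-gamma) and
    is ``-inf`` — never NaN — when a zero-probability category has a positive
    count.
    """
    counts_row = np.asarray(counts_row, dtype=np.int64)
    if counts_row.shape != (spec.n_categories,):
        raise ValueError(
            f"counts must have length {spec.n_categories}, got {counts_row.shape}"
        )
    if np.any(counts_row < 0):
        raise ValueError("counts must be non-negative")
    probs = np.concatenate(category_probabilities(spec, theta))
    total = 0.0
    off = 0
    for k, Lk in enumerate(spec.L):
        n = counts_row[off : off + Lk]
        p = probs[off : off + Lk]
        Jk = int(n.sum()) if J is None else int(np.asarray(J)[k])
        total += gammaln(Jk + 1) - gammaln(n + 1).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            total += xlogy(n, p).sum()
        off += Lk
    return float(total)


# ---------------------------------------------------------------------------
# CSV count I/O
# ---------------------------------------------------------------------------


def _column_names(spec: MptModelSpec) -> list[str]:
    return [
        f"{spec.subtree_labels[k]}.{cat}"
        for k in range(spec.K)
        for cat in spec.category_labels[k]
    ]


def write_counts_csv(table: CountTable, spec: MptModelSpec, path) -> None:
    """Write a count table as tidy CSV: participant, condition, one column per
    ``treeLabel.categoryLabel`` pair."""
    cols = _column_names(spec)
    rows = []
    for i in range(table.I):
        for c in range(table.n_conditions):
            rows.append([i + 1, c + 1] + list(table.counts[i, c]))
    df = pd.DataFrame(rows, columns=["participant", "condition"] + cols)
    df.to_csv(path, index=False)


def read_counts_csv(path, spec: MptModelSpec, J=None) -> CountTable:
    """Read a count table written by :func:`write_counts_csv`.

    Also accepts the plain one-condition layout without the ``participant`` /
    ``condition`` columns (one row per participant).
    """
    df = pd.read_csv(path)
    cols = _column_names(spec)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"count CSV is missing columns: {missing}")
    if "condition" in df.columns:
        conditions = sorted(df["condition"].unique())
        participants = sorted(df["participant"].unique())
        I, C = len(participants), len(conditions)
        counts = np.zeros((I, C, len(cols)), dtype=np.int64)
        pi = {p: i for i, p in enumerate(participants)}
        ci = {c: i for i, c in enumerate(conditions)}
        for _, row in df.iterrows():
            counts[pi[row["participant"]], ci[row["condition"]]] = row[cols].to_numpy()
    else:
        counts = df[cols].to_numpy(dtype=np.int64)[:, None, :]
    _, _, _, cat_offsets = spec.flat_structure()
    if J is None:
        J = [
            int(counts[0, 0, cat_offsets[k] : cat_offsets[k + 1]].sum())
            for k in range(spec.K)
        ]
    return CountTable.from_spec(spec, counts, J)
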