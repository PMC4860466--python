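"""Hebbian pathways between maps and lateral cross-language connections.

Associative weights are directed, start at zero, and grow by the
agreement-scaled Hebbian rule

    dw_kl = beta * alpha_k * alpha_l * N

where alpha_k, alpha_l are the activations of the source and target nodes,
N is the name agreement (proportion of speakers producing the name), and
beta is the constant Hebbian learning rate (0.2).  Unbounded growth is
prevented by multiplicative normalization: after an update, any outgoing
weight vector whose maximum exceeds 1 is rescaled so its maximum is exactly 1.

Lateral connections live within the phonological map, between node pairs that
belong to different languages; they are stored sparsely since only the BMUs of
activated names ever participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivationField",
    "AssociativeMatrix",
    "LateralMatrix",
    "hebbian_update",
    "propagate",
    "update_lateral",
]


@dataclass
class ActivationField:
    """Per-node activation pattern on one map, each value in [0, 1]."""

    map_tag: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation field contains non-finite values")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("activations must lie in [0, 1]")


@dataclass
class AssociativeMatrix:
    """Directed Hebbian weights from every source-map node to every target-map node."""

    source_tag: str
    target_tag: str
    language: str  # 'A', 'B', or 'shared'
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("associative weights must be a 2-d array")

    @classmethod
    def zeros(
        cls, source_tag: str, target_tag: str, language: str,
        n_source: int, n_target: int,
    ) -> "AssociativeMatrix":
        return cls(source_tag, target_tag, language,
                   np.zeros((n_source, n_target)))


def _normalize_rows(weights: np.ndarray, rows: np.ndarray | None = None) -> None:
    """Multiplicative cap: rescale any outgoing vector whose max exceeds 1."""
    w = weights if rows is None else weights[rows]
    mx = w.max(axis=1)
    over = mx > 1.0
    if over.any():
        w[over] /= mx[over, None]
        if rows is not None:
            weights[rows] = w


def hebbian_update(
    matrix: AssociativeMatrix,
    source_field: ActivationField,
    target_field: ActivationField,
    N: float,
    beta: float,
) -> AssociativeMatrix:
    """Agreement-scaled Hebbian increment followed by the multiplicative cap.

    Each w_kl grows by beta * alpha_k * alpha_l * N; afterwards every outgoing
    weight vector (fixed source node k) is rescaled so its maximum is <= 1.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if not 0.0 <= N <= 1.0:
        raise ValueError(f"name agreement N={N} outside [0, 1]")
    if source_field.map_tag != matrix.source_tag:
        raise ValueError(
            f"source field on map {source_field.map_tag!r}, matrix expects "
            f"{matrix.source_tag!r}"
        )
    if target_field.map_tag != matrix.target_tag:
        raise ValueError(
            f"target field on map {target_field.map_tag!r}, matrix expects "
            f"{matrix.target_tag!r}"
        )
    a_k = source_field.values
    a_l = target_field.values
    if matrix.weights.shape != (a_k.size, a_l.size):
        raise ValueError(
            f"field sizes ({a_k.size}, {a_l.size}) do not match matrix shape "
            f"{matrix.weights.shape}"
        )
    # only the co-active block changes; index it directly for speed
    src = np.nonzero(a_k)[0]
    tgt = np.nonzero(a_l)[0]
    if src.size and tgt.size:
        matrix.weights[np.ix_(src, tgt)] += beta * N * np.outer(a_k[src], a_l[tgt])
        _normalize_rows(matrix.weights, src)
    return matrix


def propagate(field: ActivationField, matrix: AssociativeMatrix) -> ActivationField:
    """Push activation through the pathway: alpha_l = clip(sum_k alpha_k w_kl)."""
    if field.map_tag != matrix.source_tag:
        raise ValueError(
            f"field on map {field.map_tag!r}, matrix source is {matrix.source_tag!r}"
        )
    if field.values.size != matrix.weights.shape[0]:
        raise ValueError("field size does not match matrix source size")
    out = np.clip(field.values @ matrix.weights, 0.0, 1.0)
    return ActivationField(map_tag=matrix.target_tag, values=out)


@dataclass
class LateralMatrix:
    """Sparse directed weights between phonological nodes of different languages.

    Keys are (source_node, target_node) pairs; self-connections are never
    created and weights stay in [0, 1] via the same multiplicative cap,
    applied per outgoing vector.
    """

    weights: dict[tuple[int, int], float] = field(default_factory=dict)

    def get(self, k: int, l: int) -> float:
        return self.weights.get((k, l), 0.0)

    def propagate(self, field_values: np.ndarray) -> np.ndarray:
        """alpha_l = clip(sum_k alpha_k w_kl) over the stored connections."""
        out = np.zeros_like(field_values, dtype=float)
        for (k, l), w in sorted(self.weights.items()):  # fixed summation order
            a = field_values[k]
            if a:
                out[l] += a * w
        return np.clip(out, 0.0, 1.0)

    def _cap(self, sources: set[int]) -> None:
        for k in sources:
            targets = [kl for kl in self.weights if kl[0] == k]
            if not targets:
                continue
            mx = max(self.weights[kl] for kl in targets)
            if mx > 1.0:
                for kl in targets:
                    self.weights[kl] /= mx


def update_lateral(
    lateral: LateralMatrix,
    phon_field_a: ActivationField,
    phon_field_b: ActivationField,
    beta: float,
) -> LateralMatrix:
    """Strengthen both directions between co-active cross-language node pairs.

    The two fields carry the activations of nodes attributed to language A and
    language B respectively; their active node sets must not overlap (a node
    cannot belong to both languages at once).  Each cross-language pair (a, b)
    with alpha_a * alpha_b > 0 gains beta * alpha_a * alpha_b in both
    directions, followed by the multiplicative cap.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    va, vb = phon_field_a.values, phon_field_b.values
    if va.shape != vb.shape:
        raise ValueError("the two phonological fields must cover the same map")
    act_a = np.nonzero(va)[0]
    act_b = np.nonzero(vb)[0]
    overlap = set(act_a.tolist()) & set(act_b.tolist())
    if overlap:
        raise ValueError(
            f"nodes {sorted(overlap)} are active in both language fields"
        )
    touched: set[int] = set()
    for a in act_a:
        for b in act_b:
            inc = beta * va[a] * vb[b]
            ia, ib = int(a), int(b)
            lateral.weights[(ia, ib)] = lateral.get(ia, ib) + inc
            lateral.weights[(ib, ia)] = lateral.get(ib, ia) + inc
            touched.update((ia, ib))
    lateral._cap(touched)
    return lateral
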