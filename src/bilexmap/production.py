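"""Simulated object naming through the trained network.

Presenting an object activates a Gaussian bump around its semantic BMU; that
activation reaches the phonological map along three routes whose sum is the
total activation of each candidate name:

* semantic route — through the target language's semantic-phonological
  Hebbian pathway (the agreement-weighted direct route);
* lateral route — through the *other* language's semantic-phonological
  pathway and then across the lateral connections into target-language nodes;
* orthographic route — through the semantic-orthographic pathway, spread over
  orthographic neighbors within the spreading radius (minimum 3), and fed
  back through the orthography-phonology pathway.

The activation read at a target-language word's phonological BMU is its
simulated name agreement; the dominant-name rule keeps the top-scoring name
plus any name scoring more than 80% of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GROUP_BILINGUAL, GROUP_MONO_A, GROUP_MONO_B, NamingDataset
from .hebbian import ActivationField, propagate
from .som import neighborhood_field
from .trainer import (
    MAP_ORTHOGRAPHIC,
    MAP_SEMANTIC,
    ModelState,
)

__all__ = [
    "CandidateRecord",
    "NamingResult",
    "name_object",
    "dominant_names",
    "empirical_dominants",
    "naming_accuracy",
    "simulated_distribution",
]


@dataclass(frozen=True)
class CandidateRecord:
    """Per-candidate activation with its three-route decomposition."""

    word: str
    sem_term: float
    lateral_term: float
    ortho_term: float
    in_weight: float  # summed associative in-weight at the BMU (tie-break key)

    @property
    def actp(self) -> float:
        return self.sem_term + self.lateral_term + self.ortho_term


@dataclass
class NamingResult:
    """Outcome of naming one object in one target language."""

    object_id: str
    target_language: str
    candidates: list[CandidateRecord]
    ties: list[tuple[str, str]] = field(default_factory=list)
    no_response: bool = False

    @property
    def simulated_agreement(self) -> dict[str, float]:
        return {c.word: c.actp for c in self.candidates}

    def ranked(self) -> list[CandidateRecord]:
        return sorted(self.candidates, key=lambda c: (-c.actp, -c.in_weight, c.word))


def _orthographic_spread(state: ModelState, values: np.ndarray) -> np.ndarray:
    """Neighborhood spreading on the orthographic map.

    A node's spread activation is the sum of its activated neighbors'
    activations within the spreading radius (the training radius, floored at
    3 so orthographically similar forms keep interacting at test time).
    """
    grid = state.maps[MAP_ORTHOGRAPHIC]
    r = max(state.config.ortho_spread_radius_floor,
            state.radius[MAP_ORTHOGRAPHIC].radius)
    d2 = grid.grid_dist2()
    mask = (d2 <= float(r) ** 2) & (d2 > 0)  # neighbors, excluding the node itself
    return np.clip(mask @ values, 0.0, 1.0)


def name_object(
    model: ModelState, object_id: str, target_language: str
) -> NamingResult:
    """Propagate one object through the network and score candidate names."""
    if model.epoch == 0:
        raise ValueError("model has not been trained")
    if object_id not in model.object_bmu:
        raise KeyError(f"unknown object {object_id!r}")
    if target_language not in model.languages:
        raise ValueError(
            f"language {target_language!r} not in model languages {model.languages}"
        )

    s_grid = model.maps[MAP_SEMANTIC]
    sem_field = ActivationField(
        MAP_SEMANTIC,
        neighborhood_field(s_grid, model.object_bmu[object_id],
                           model.radius[MAP_SEMANTIC].radius),
    )

    # (1) semantic route: target language's S->P pathway
    sem_route = propagate(sem_field, model.assoc[f"S->P/{target_language}"]).values

    # (2) lateral route: the other language's pathway, then across languages
    n_nodes = s_grid.n_nodes
    lateral_route = np.zeros(n_nodes)
    non_target = [l for l in model.languages if l != target_language]
    if model.has_lateral and non_target:
        nt = non_target[0]
        nt_phon = propagate(sem_field, model.assoc[f"S->P/{nt}"]).values
        labeling = model.language_labeling()
        restricted = np.zeros(n_nodes)
        for node, lang in labeling.items():
            if lang == nt:
                restricted[node] = nt_phon[node]
        lateral_route = model.lateral.propagate(restricted)

    # (3) orthographic route: S->O, neighborhood spreading, feed back O->P
    ortho_route = np.zeros(n_nodes)
    if model.has_orthography:
        o_field = propagate(sem_field, model.assoc["S->O"]).values
        spread = _orthographic_spread(model, o_field)
        ortho_route = propagate(
            ActivationField(MAP_ORTHOGRAPHIC, spread), model.assoc["O->P"]
        ).values

    sp = model.assoc[f"S->P/{target_language}"].weights
    candidates = []
    bmu_owner: dict[int, str] = {}
    ties: list[tuple[str, str]] = []
    for word in model.words_of(target_language):
        bmu = model.word_bmu_phon[word]
        if bmu in bmu_owner:
            ties.append((bmu_owner[bmu], word))
        else:
            bmu_owner[bmu] = word
        candidates.append(CandidateRecord(
            word=word,
            sem_term=float(sem_route[bmu]),
            lateral_term=float(lateral_route[bmu]),
            ortho_term=float(ortho_route[bmu]),
            in_weight=float(sp[:, bmu].sum()),
        ))
    no_response = all(c.actp == 0.0 for c in candidates)
    return NamingResult(
        object_id=object_id,
        target_language=target_language,
        candidates=candidates,
        ties=ties,
        no_response=no_response,
    )


def dominant_names(result: NamingResult) -> set[str]:
    """The argmax name plus any name scoring more than 80% of the maximum."""
    scores = result.simulated_agreement
    if not scores or max(scores.values()) <= 0.0:
        raise ValueError(
            f"no positive activation for object {result.object_id!r}; "
            "cannot determine a dominant name"
        )
    top = result.ranked()[0]
    return {w for w, s in scores.items() if s > 0.8 * top.actp} | {top.word}


def _dominants_from_scores(scores: dict[str, float]) -> set[str]:
    mx = max(scores.values())
    best = min(w for w, s in scores.items() if s == mx)
    return {w for w, s in scores.items() if s > 0.8 * mx} | {best}


def empirical_dominants(
    dataset: NamingDataset, group: str, language: str
) -> dict[str, set[str]]:
    """Per-object dominant-name sets under the same 80% rule, from the norms."""
    agr = dataset.agreements(group, language)
    out: dict[str, set[str]] = {}
    for obj, row in agr.iterrows():
        scores = {w: float(v) for w, v in row.items() if v > 0}
        if scores:
            out[str(obj)] = _dominants_from_scores(scores)
    return out


def _default_group(model: ModelState) -> str:
    if model.config.condition == "monolingual_A":
        return GROUP_MONO_A
    if model.config.condition == "monolingual_B":
        return GROUP_MONO_B
    return GROUP_BILINGUAL


def naming_accuracy(
    model: ModelState,
    dataset: NamingDataset,
    language: str,
    group: str | None = None,
) -> float:
    """Percentage of objects whose simulated dominant set meets the empirical one.

    The empirical dominant sets come from the naming norms of ``group``
    (defaults to the group matching the model's condition); objects without
    empirical responses in that group are excluded, and objects the model
    cannot name (no positive activation) count as misses.
    """
    group = group or _default_group(model)
    truth = empirical_dominants(dataset, group, language)
    if not truth:
        raise ValueError(f"no responses for group {group!r} in language {language!r}")
    hits = 0
    for obj, expected in truth.items():
        result = name_object(model, obj, language)
        if result.no_response:
            continue
        if dominant_names(result) & expected:
            hits += 1
    return 100.0 * hits / len(truth)


def simulated_distribution(model: ModelState, language: str) -> "np.ndarray":
    """(n_objects x n_words) matrix of simulated name agreements.

    Rows follow the model's object order, columns the language's word order;
    this is the simulated analogue of a group's name-distribution table.
    """
    words = model.words_of(language)
    out = np.zeros((len(model.object_ids), len(words)))
    for i, obj in enumerate(model.object_ids):
        result = name_object(model, obj, language)
        agreement = result.simulated_agreement
        for j, w in enumerate(words):
            out[i, j] = agreement[w]
    return out
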