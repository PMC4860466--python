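"""Checksummed state archives and run manifests.

A model archive is a zip container holding a compressed bundle of named
numeric arrays (map weights, pathway matrices, registries, input encodings)
plus a JSON header (config, seeds, logs, RNG state) and a SHA-256 checksum of
both.  Round-trips are bit-identical, so naming outputs before a save equal
naming outputs after a load.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .hebbian import AssociativeMatrix, LateralMatrix
from .som import MapGrid, NeighborhoodState, TrainingSchedule
from .trainer import ModelState, TrainingConfig

__all__ = [
    "ARCHIVE_VERSION",
    "CorruptArchiveError",
    "VersionMismatchError",
    "save_state",
    "load_state",
    "states_equal",
    "RunManifest",
]

ARCHIVE_VERSION = 1


class CorruptArchiveError(RuntimeError):
    """The archive is truncated or its checksum does not match."""


class VersionMismatchError(RuntimeError):
    """The archive was written by an incompatible format version."""


def _config_to_dict(config: TrainingConfig) -> dict:
    return asdict(config)


def _config_from_dict(d: dict) -> TrainingConfig:
    d = dict(d)
    schedule = TrainingSchedule(**d.pop("schedule"))
    return TrainingConfig(schedule=schedule, **d)


def save_state(state: ModelState, path: str | Path) -> Path:
    """Write a checksummed archive of the full model state."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for tag, grid in state.maps.items():
        arrays[f"map/{tag}"] = grid.weights
    for key, mat in state.assoc.items():
        arrays[f"assoc/{key}"] = mat.weights
    if state.lateral is not None:
        items = sorted(state.lateral.weights.items())
        arrays["lateral/keys"] = np.array([k for k, _ in items], dtype=np.int64).reshape(-1, 2)
        arrays["lateral/values"] = np.array([v for _, v in items], dtype=float)
    arrays["features"] = state.features
    arrays["phon_vecs"] = state.phon_vecs
    arrays["orth_vecs"] = state.orth_vecs
    for lang, agr in state.agreements.items():
        arrays[f"agreements/{lang}"] = agr

    buf = io.BytesIO()
    np.savez_compressed(buf, **arrays)
    array_bytes = buf.getvalue()

    meta = {
        "version": ARCHIVE_VERSION,
        "config": _config_to_dict(state.config),
        "seed": state.seed,
        "epoch": state.epoch,
        "languages": state.languages,
        "maps": {tag: {"rows": g.rows, "cols": g.cols, "dim": g.dim,
                       "rng_seed": g.rng_seed}
                 for tag, g in state.maps.items()},
        "assoc": {key: {"source": m.source_tag, "target": m.target_tag,
                        "language": m.language}
                  for key, m in state.assoc.items()},
        "has_lateral": state.lateral is not None,
        "radius": {tag: {"radius": r.radius, "radius_floor": r.radius_floor,
                         "check_interval": r.check_interval,
                         "qe_history": r.qe_history}
                   for tag, r in state.radius.items()},
        "object_ids": state.object_ids,
        "word_ids": state.word_ids,
        "word_langs": state.word_langs,
        "object_bmu": state.object_bmu,
        "word_bmu_phon": state.word_bmu_phon,
        "word_bmu_orth": state.word_bmu_orth,
        "log": state.log,
        "rng_state": json.loads(json.dumps(state.rng_state, default=int)),
    }
    meta_bytes = json.dumps(meta).encode()
    checksum = hashlib.sha256(array_bytes + meta_bytes).hexdigest()

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("arrays.npz", array_bytes)
        zf.writestr("meta.json", meta_bytes)
        zf.writestr("checksum.txt", checksum)
    return path


def load_state(path: str | Path) -> ModelState:
    """Read and verify an archive written by :func:`save_state`."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            array_bytes = zf.read("arrays.npz")
            meta_bytes = zf.read("meta.json")
            stored = zf.read("checksum.txt").decode().strip()
    except (zipfile.BadZipFile, KeyError, OSError) as exc:
        raise CorruptArchiveError(f"unreadable archive {path}: {exc}") from exc
    actual = hashlib.sha256(array_bytes + meta_bytes).hexdigest()
    if actual != stored:
        raise CorruptArchiveError(f"checksum mismatch in {path}")
    meta = json.loads(meta_bytes)
    if meta.get("version") != ARCHIVE_VERSION:
        raise VersionMismatchError(
            f"archive version {meta.get('version')} != {ARCHIVE_VERSION}"
        )
    npz = np.load(io.BytesIO(array_bytes))

    maps = {}
    for tag, info in meta["maps"].items():
        maps[tag] = MapGrid(rows=info["rows"], cols=info["cols"], dim=info["dim"],
                            weights=npz[f"map/{tag}"], rng_seed=info["rng_seed"])
    assoc = {}
    for key, info in meta["assoc"].items():
        assoc[key] = AssociativeMatrix(
            source_tag=info["source"], target_tag=info["target"],
            language=info["language"], weights=npz[f"assoc/{key}"],
        )
    lateral = None
    if meta["has_lateral"]:
        lateral = LateralMatrix()
        if "lateral/keys" in npz:
            keys = npz["lateral/keys"]
            values = npz["lateral/values"]
            lateral.weights = {
                (int(k[0]), int(k[1])): float(v) for k, v in zip(keys, values)
            }
    radius = {
        tag: NeighborhoodState(
            radius=info["radius"], radius_floor=info["radius_floor"],
            check_interval=info["check_interval"],
            qe_history=list(info["qe_history"]),
        )
        for tag, info in meta["radius"].items()
    }
    return ModelState(
        config=_config_from_dict(meta["config"]),
        seed=meta["seed"],
        epoch=meta["epoch"],
        languages=list(meta["languages"]),
        maps=maps,
        radius=radius,
        assoc=assoc,
        lateral=lateral,
        object_ids=list(meta["object_ids"]),
        features=npz["features"],
        word_ids=list(meta["word_ids"]),
        word_langs=list(meta["word_langs"]),
        phon_vecs=npz["phon_vecs"],
        orth_vecs=npz["orth_vecs"],
        agreements={lang: npz[f"agreements/{lang}"] for lang in meta["languages"]},
        object_bmu={k: int(v) for k, v in meta["object_bmu"].items()},
        word_bmu_phon={k: int(v) for k, v in meta["word_bmu_phon"].items()},
        word_bmu_orth={k: int(v) for k, v in meta["word_bmu_orth"].items()},
        log=list(meta["log"]),
        rng_state=meta["rng_state"],
    )


def states_equal(a: ModelState, b: ModelState) -> bool:
    """Field-by-field equality of two model states (arrays compared exactly)."""
    if set(a.maps) != set(b.maps) or set(a.assoc) != set(b.assoc):
        return False
    for tag in a.maps:
        if not np.array_equal(a.maps[tag].weights, b.maps[tag].weights):
            return False
    for key in a.assoc:
        if not np.array_equal(a.assoc[key].weights, b.assoc[key].weights):
            return False
    if (a.lateral is None) != (b.lateral is None):
        return False
    if a.lateral is not None and a.lateral.weights != b.lateral.weights:
        return False
    return (
        a.epoch == b.epoch
        and a.seed == b.seed
        and a.languages == b.languages
        and a.object_ids == b.object_ids
        and a.word_ids == b.word_ids
        and a.word_langs == b.word_langs
        and a.object_bmu == b.object_bmu
        and a.word_bmu_phon == b.word_bmu_phon
        and a.word_bmu_orth == b.word_bmu_orth
        and np.array_equal(a.features, b.features)
        and np.array_equal(a.phon_vecs, b.phon_vecs)
        and np.array_equal(a.orth_vecs, b.orth_vecs)
        and all(np.array_equal(a.agreements[l], b.agreements[l]) for l in a.agreements)
        and {t: r.radius for t, r in a.radius.items()}
        == {t: r.radius for t, r in b.radius.items()}
    )


@dataclass
class RunManifest:
    """Record of a pipeline run, sufficient to re-run it bit-identically."""

    command: str
    config: dict
    seeds: list[int]
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    logs: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
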