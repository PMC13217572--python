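"""End-to-end orchestration: read, preprocess, enumerate, classify, report.

The full pipeline mirrors the four conceptual stages of the method —
elementary circuit enumeration, assembly of CS-equivalence class
representatives, autocatalysis testing, and core identification — applied
per strongly connected component, optionally with spectral partitioning for
large components.  Results are serialized as one JSON line per class plus a
size-distribution summary table; re-running with the same configuration and
inputs yields byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import assembly, autocat, circuits, konig, partition as partition_mod
from .crn import CRN, read_model, remove_species, resolve_catalysts, split_reversible
from .konig import Edge, species_vertex, reaction_vertex, vertex_id

logger = logging.getLogger("autocatnet")

__all__ = ["RunConfig", "run_full", "run_summary", "key_to_json", "key_from_json"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    ``max_species`` caps the subnetwork size (species per class); the
    corresponding circuit length cap is twice that in total vertices.  The
    seed is used only by fixture generation — the pipeline itself is
    deterministic.
    """

    input: str = ""
    format: str | None = None
    blacklist: str | None = None
    catalyst_policy: str = "net"
    min_reactions: int = 2
    max_species: int | None = None
    mode: str = "full"
    max_module: int | None = None
    max_len_intra: int | None = None
    max_len_cross: int | None = None
    workers: int = 1
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"full", "cores_only"}:
            raise ValueError(f"invalid mode {self.mode!r}")
        for name in ("max_species", "max_module", "max_len_intra", "max_len_cross"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be positive")
        if self.min_reactions < 0:
            raise ValueError("min_reactions must be >= 0")

    # simple `key = value` round-trip serialization ------------------------

    _NONE = "none"

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {self._NONE if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            if val == cls._NONE:
                kwargs[key] = None
            elif "int" in str(types[key]):
                kwargs[key] = int(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def key_to_json(e1: frozenset[Edge]) -> list[list[str]]:
    return sorted([vertex_id(u), vertex_id(v)] for u, v in e1)


def key_from_json(pairs: Iterable[list[str]]) -> frozenset[Edge]:
    return frozenset((species_vertex(x), reaction_vertex(r)) for x, r in pairs)


def _class_record(cls: assembly.FluffleClass) -> dict:
    return {
        "e1": key_to_json(cls.e1),
        "n_species": cls.size,
        "circuit": cls.is_circuit,
        "metzler": cls.metzler,
        "autocatalytic": cls.autocatalytic,
        "core": cls.core,
        "predecessors": sorted(key_to_json(k) for k in cls.predecessors),
    }


def _summarize(records: list[dict]) -> pd.DataFrame:
    """Size-distribution table: counts per (size, category)."""
    rows = []
    sizes = sorted({r["n_species"] for r in records})
    for size in sizes:
        at = [r for r in records if r["n_species"] == size]
        rows.append(
            {
                "size": size,
                "circuit_classes": sum(1 for r in at if r["circuit"]),
                "fluffle_classes": len(at),
                "autocat_metzler": sum(
                    1 for r in at if r["autocatalytic"] and r["metzler"]
                ),
                "autocat_nonmetzler": sum(
                    1 for r in at if r["autocatalytic"] and not r["metzler"]
                ),
                "cores": sum(1 for r in at if r["core"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "size", "circuit_classes", "fluffle_classes",
            "autocat_metzler", "autocat_nonmetzler", "cores",
        ],
    )


def run_full(config: RunConfig) -> dict:
    """Execute the pipeline described by ``config`` and return a report.

    The report carries network/counting statistics, the per-class records,
    the summary table, and per-stage wall-clock timings (informational
    only).  When ``config.outdir`` is set, ``classes.jsonl`` and
    ``summary.tsv`` are written there with stable ordering.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def mark(stage: str) -> None:
        nonlocal t0
        t1 = time.perf_counter()
        timings[stage] = t1 - t0
        logger.info("stage %-12s %.3fs", stage, t1 - t0)
        t0 = t1

    crn = read_model(config.input, config.format)
    if config.blacklist:
        ids = [
            ln.strip()
            for ln in Path(config.blacklist).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        crn = remove_species(crn, ids)
    crn = split_reversible(crn)
    crn = resolve_catalysts(crn, config.catalyst_policy)
    mark("preprocess")

    kg = konig.build_konig(crn)
    comps = konig.filter_components(
        konig.strongly_connected_components(kg), config.min_reactions
    )
    mark("components")

    max_len = None if config.max_species is None else 2 * config.max_species
    n_circuits = 0
    all_classes: list[assembly.FluffleClass] = []
    cores: list[assembly.FluffleClass] = []
    for comp in comps:
        if config.mode == "cores_only":
            comp_cores = autocat.enumerate_cores_direct(comp, crn, config.max_species)
            cores.extend(comp_cores)
            all_classes.extend(comp_cores)
            continue
        if config.max_module is not None:
            tree = partition_mod.partition_network(comp, config.max_module)
            idx = partition_mod.modular_circuit_enumeration(
                comp,
                tree,
                config.max_len_intra or max_len or len(comp.vertexset),
                config.max_len_cross or max_len or len(comp.vertexset),
            )
        else:
            idx = circuits.enumerate_elementary_circuits(comp, max_len)
        n_circuits += len(idx)
        reps = circuits.circuit_representatives(idx)
        classes = assembly.assemble_classes(reps, comp, config.max_species)
        cores.extend(autocat.identify_cores(classes, crn, comp))
        all_classes.extend(classes.values())
    mark("enumerate")

    all_classes.sort(key=lambda c: (c.size, c.sorted_key()))
    records = [_class_record(c) for c in all_classes]
    summary = _summarize(records)
    report = {
        "n_species": len(crn.species),
        "n_reactions": len(crn.reactions),
        "n_components": len(comps),
        "n_circuits": n_circuits,
        "n_classes": len(all_classes) if config.mode == "full" else None,
        "n_autocatalytic": (
            sum(1 for c in all_classes if c.autocatalytic)
            if config.mode == "full"
            else None
        ),
        "n_autocat_metzler": (
            sum(1 for c in all_classes if c.autocatalytic and c.metzler)
            if config.mode == "full"
            else None
        ),
        "n_autocat_nonmetzler": (
            sum(1 for c in all_classes if c.autocatalytic and not c.metzler)
            if config.mode == "full"
            else None
        ),
        "n_cores": len(cores),
        "classes": records,
        "summary": summary,
        "timings": timings,
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "classes.jsonl", "w") as fh:
            for rec in records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        logger.info("wrote %s and %s", outdir / "classes.jsonl", outdir / "summary.tsv")
    return report


def run_summary(results_path: str | Path) -> pd.DataFrame:
    """Rebuild the size-distribution table from a ``classes.jsonl`` file."""
    path = Path(results_path)
    if not path.exists():
        raise FileNotFoundError(f"no such results file: {path}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise OSError(f"{path}:{lineno}: corrupt results line") from exc
    return _summarize(records)
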