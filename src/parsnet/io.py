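"""Readers and writers for the tool's file formats.

Primary interchange is TSV: reaction tables (``reaction_id<TAB>comma-separated
metabolite ids``), annotation tables (``enzyme_id<TAB>comma-separated reaction
ids``), per-sample enzyme abundances (``enzyme_id<TAB>count``), marginal
profiles (``reaction_id<TAB>probability``), and square labeled distance
matrices.  A single JSON document mirrors the network tables for programmatic
use.  Dendrograms are written as Newick (readable by phylogenetics viewers),
reaction graphs as GraphML.  ``#``-prefixed comment lines and blank lines are
ignored on input; all files are UTF-8.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .comparative import Dendrogram, DistanceMatrix
from .network import AnnotatedMetabolicNetwork, build_network
from .sampler import MarginalProfile

__all__ = [
    "FormatError",
    "RunManifest",
    "read_network_tsv",
    "write_network_tsv",
    "read_network_json",
    "write_network_json",
    "read_abundance_tsv",
    "read_marginals",
    "write_marginals",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_newick",
    "write_graphml",
    "read_groups_tsv",
]


class FormatError(ValueError):
    """Malformed input file; message carries the path and line number."""


def _data_lines(path: Path) -> list[tuple[int, str]]:
    out = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        out.append((lineno, line))
    return out


def _parse_set_table(path: Path, kind: str) -> list[tuple[str, list[str]]]:
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip():
            raise FormatError(
                f"{path}:{lineno}: expected '{kind}_id<TAB>comma-separated ids', "
                f"got {line!r}"
            )
        members = [x.strip() for x in parts[1].split(",") if x.strip()]
        if not members:
            raise FormatError(f"{path}:{lineno}: empty member list for {parts[0]!r}")
        rows.append((parts[0].strip(), members))
    return rows


def read_network_tsv(
    reactions_path: str | Path, annotations_path: str | Path
) -> AnnotatedMetabolicNetwork:
    """Build a network from reaction and annotation TSV files."""
    rxn = _parse_set_table(Path(reactions_path), "reaction")
    enz = _parse_set_table(Path(annotations_path), "enzyme")
    return build_network(rxn, enz)


def write_network_tsv(
    network: AnnotatedMetabolicNetwork,
    reactions_path: str | Path,
    annotations_path: str | Path,
) -> None:
    with open(reactions_path, "w", encoding="utf-8") as fh:
        fh.write("# reaction_id\tmetabolite_ids\n")
        for rid in network.reaction_ids:
            fh.write(f"{rid}\t{','.join(sorted(network.reactions[rid].metabolites))}\n")
    with open(annotations_path, "w", encoding="utf-8") as fh:
        fh.write("# enzyme_id\treaction_ids\n")
        for eid in sorted(network.enzymes):
            fh.write(f"{eid}\t{','.join(sorted(network.enzymes[eid].reactions))}\n")


def read_network_json(path: str | Path) -> AnnotatedMetabolicNetwork:
    """JSON mirror: ``{"reactions": {id: [mets]}, "enzymes": {id: [rxns]}}``."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        reactions = {str(k): list(v) for k, v in doc["reactions"].items()}
        enzymes = {str(k): list(v) for k, v in doc["enzymes"].items()}
    except (KeyError, TypeError, AttributeError) as exc:
        raise FormatError(f"{path}: expected 'reactions' and 'enzymes' maps") from exc
    return build_network(reactions, enzymes)


def write_network_json(network: AnnotatedMetabolicNetwork, path: str | Path) -> None:
    doc = {
        "reactions": {
            rid: sorted(network.reactions[rid].metabolites)
            for rid in network.reaction_ids
        },
        "enzymes": {
            eid: sorted(network.enzymes[eid].reactions)
            for eid in sorted(network.enzymes)
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_abundance_tsv(path: str | Path) -> dict[str, float]:
    """Per-sample enzyme abundances: ``enzyme_id<TAB>count``."""
    out: dict[str, float] = {}
    p = Path(path)
    for lineno, line in _data_lines(p):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{p}:{lineno}: expected 'enzyme_id<TAB>count'")
        try:
            value = float(parts[1])
        except ValueError:
            raise FormatError(f"{p}:{lineno}: count {parts[1]!r} is not a number")
        if value < 0:
            raise FormatError(f"{p}:{lineno}: negative count")
        if parts[0] in out:
            raise FormatError(f"{p}:{lineno}: duplicate enzyme id {parts[0]!r}")
        out[parts[0]] = value
    return out


def write_marginals(
    profile: MarginalProfile,
    path: str | Path,
    header: Mapping[str, object] | None = None,
) -> None:
    """Marginal-probability TSV with a ``#`` config header, 6 decimals."""
    meta = dict(profile.config_summary)
    if header:
        meta.update(header)
    with open(path, "w", encoding="utf-8") as fh:
        if profile.sample_id:
            fh.write(f"# sample_id = {profile.sample_id}\n")
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# reaction_id\tprobability\n")
        for rid in sorted(profile.probabilities):
            fh.write(f"{rid}\t{profile.probabilities[rid]:.6f}\n")


def read_marginals(path: str | Path, sample_id: str = "") -> MarginalProfile:
    probs: dict[str, float] = {}
    meta: dict[str, str] = {}
    p = Path(path)
    for lineno, raw in enumerate(p.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{p}:{lineno}: expected 'reaction_id<TAB>probability'")
        try:
            value = float(parts[1])
        except ValueError:
            raise FormatError(f"{p}:{lineno}: probability {parts[1]!r} is not a number")
        if not 0.0 <= value <= 1.0:
            raise FormatError(f"{p}:{lineno}: probability {value} outside [0, 1]")
        if parts[0] in probs:
            raise FormatError(f"{p}:{lineno}: duplicate reaction id {parts[0]!r}")
        probs[parts[0]] = value
    sid = sample_id or meta.pop("sample_id", "") or p.stem
    return MarginalProfile(probabilities=probs, sample_id=sid, config_summary=meta)


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column labels differ")
    return DistanceMatrix(tuple(str(s) for s in df.index), df.to_numpy(dtype=float))


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n", encoding="utf-8")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    """Group assignment: ``sample_id<TAB>group_name``."""
    out: dict[str, str] = {}
    p = Path(path)
    for lineno, line in _data_lines(p):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{p}:{lineno}: expected 'sample_id<TAB>group'")
        if parts[0] in out:
            raise FormatError(f"{p}:{lineno}: duplicate sample id {parts[0]!r}")
        out[parts[0]] = parts[1]
    return out


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    tool: str
    version: str
    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    input_checksums: dict[str, str] = field(default_factory=dict)
    acceptance_rate: float | None = None
    timestamp: str = ""

    @staticmethod
    def checksum(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    @classmethod
    def create(
        cls,
        command: str,
        config: Mapping[str, object],
        inputs: Mapping[str, str | Path] | None = None,
        seed: int | None = None,
        acceptance_rate: float | None = None,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            tool="parsnet",
            version=__version__,
            command=command,
            config=dict(config),
            seed=seed,
            input_checksums={
                name: cls.checksum(p) for name, p in (inputs or {}).items()
            },
            acceptance_rate=acceptance_rate,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, default=str) + "\n", encoding="utf-8"
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
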