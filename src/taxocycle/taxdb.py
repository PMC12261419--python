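"""Precomputed taxon database: archive format, construction, rank fallback.

A database archive is a zip file holding, per included taxon, a consensus
proteome FASTA and an annotation TSV, plus a root ``index.tsv`` with
columns ``taxon_name``, ``rank``, ``proteome_count``, ``proteome_path``,
``annotation_path``.  Taxa enter the archive only when backed by at least
``min_proteomes`` source proteomes (default 5).

Taxonomic affiliations are resolved against the index most-specific-rank
first: the first (name, rank) pair of the lineage, walking species ->
kingdom, that exists in the index wins.  An unresolved affiliation is a
normal outcome, not an error.  Name matching is exact after whitespace
trimming and case-sensitive; homonyms at different ranks are
disambiguated by the (name, rank) pair.
"""

from __future__ import annotations

import json
import logging
import re
import zipfile
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Rank",
    "RANK_ORDER",
    "TaxonomicAffiliation",
    "TaxonIndexEntry",
    "ProteinCluster",
    "TaxonRecord",
    "ResolutionResult",
    "AffiliationError",
    "DatabaseError",
    "parse_affiliations",
    "create_db",
    "load_index",
    "resolve_affiliation",
    "load_taxon_record",
    "summarize_database",
    "summarize_index",
    "write_resolution_report",
]


class Rank(str, Enum):
    """The seven-slot lineage convention, broad to specific."""

    KINGDOM = "kingdom"
    PHYLUM = "phylum"
    CLASS = "class"
    ORDER = "order"
    FAMILY = "family"
    GENUS = "genus"
    SPECIES = "species"

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        label = label.strip().lower()
        if label == "domain":  # common synonym in 16S lineages
            label = "kingdom"
        return cls(label)


RANK_ORDER: tuple[Rank, ...] = tuple(Rank)


class AffiliationError(ValueError):
    """Malformed affiliation input."""


class DatabaseError(ValueError):
    """Malformed or inconsistent database archive."""


@dataclass(frozen=True)
class TaxonomicAffiliation:
    observation_id: str
    lineage: tuple[tuple[Rank, str], ...]  # ordered broad -> specific

    def __post_init__(self):
        if not self.lineage:
            raise AffiliationError(f"{self.observation_id}: empty lineage")
        order = [RANK_ORDER.index(r) for r, _ in self.lineage]
        if order != sorted(set(order)):
            raise AffiliationError(
                f"{self.observation_id}: lineage ranks must strictly increase in specificity"
            )
        if any(not name.strip() for _, name in self.lineage):
            raise AffiliationError(f"{self.observation_id}: blank lineage name")

    @property
    def most_specific(self) -> tuple[Rank, str]:
        return self.lineage[-1]


@dataclass(frozen=True)
class TaxonIndexEntry:
    taxon_name: str
    rank: Rank
    proteome_count: int
    proteome_path: str = ""
    annotation_path: str = ""


@dataclass(frozen=True)
class ProteinCluster:
    cluster_id: str
    consensus_sequence: str
    member_protein_ids: tuple[str, ...]
    annotations: tuple[str, ...] = ()


@dataclass(frozen=True)
class TaxonRecord:
    taxon_name: str
    rank: Rank
    clusters: tuple[ProteinCluster, ...]
    proteome_count: int


@dataclass(frozen=True)
class ResolutionResult:
    observation_id: str
    status: str  # "resolved" | "unresolved"
    matched_taxon: TaxonIndexEntry | None = None
    matched_rank: Rank | None = None


# ---------------------------------------------------------------------------
# Affiliation parsing
# ---------------------------------------------------------------------------

def parse_affiliations(
    path: str | Path,
    *,
    header: bool = True,
    align: str = "left",
) -> list[TaxonomicAffiliation]:
    """Parse a tabulated affiliation file.

    Two columns: observation id and semicolon-separated lineage, ordered
    broad to specific.  Ranks are assigned positionally into the
    seven-slot kingdom->species convention: ``align="left"`` anchors the
    first element at kingdom (a 3-element lineage ends at class),
    ``align="right"`` anchors the last element at species.
    """
    if align not in ("left", "right"):
        raise ValueError("align must be 'left' or 'right'")
    affiliations: list[TaxonomicAffiliation] = []
    seen: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    start = 1 if header else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise AffiliationError(f"line {lineno}: expected >= 2 tab-separated columns")
        obs_id = fields[0].strip()
        if not obs_id:
            raise AffiliationError(f"line {lineno}: empty observation id")
        if obs_id in seen:
            raise AffiliationError(
                f"line {lineno}: duplicate observation id {obs_id!r} "
                f"(first seen at line {seen[obs_id]})"
            )
        seen[obs_id] = lineno
        names = [t.strip() for t in fields[1].split(";") if t.strip()]
        if not names:
            raise AffiliationError(f"empty lineage at line {lineno}")
        if len(names) > len(RANK_ORDER):
            raise AffiliationError(
                f"line {lineno}: lineage has {len(names)} levels, more than "
                f"the {len(RANK_ORDER)}-rank convention"
            )
        if align == "left":
            ranks = RANK_ORDER[: len(names)]
        else:
            ranks = RANK_ORDER[len(RANK_ORDER) - len(names):]
        affiliations.append(
            TaxonomicAffiliation(observation_id=obs_id, lineage=tuple(zip(ranks, names)))
        )
    return affiliations


# ---------------------------------------------------------------------------
# Archive construction and access
# ---------------------------------------------------------------------------

_SAFE_TOKEN = re.compile(r"[^A-Za-z0-9_.-]+")
# Fixed timestamp so identical inputs produce byte-identical archives.
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


def _sanitize(name: str, taken: set[str]) -> str:
    token = _SAFE_TOKEN.sub("_", name).strip("_") or "taxon"
    candidate, k = token, 1
    while candidate in taken:
        k += 1
        candidate = f"{token}_{k}"
    taken.add(candidate)
    return candidate


def _read_taxon_folder(folder: Path) -> tuple[str, Rank, int, str, str]:
    meta_path = folder / "metadata.json"
    if not meta_path.exists():
        raise DatabaseError(f"{folder}: missing metadata.json")
    meta = json.loads(meta_path.read_text())
    name = meta["taxon_name"]
    rank = Rank.from_label(meta["rank"])
    count = int(meta["proteome_count"])
    if count < 0:
        raise DatabaseError(f"{name}: negative proteome_count")
    fasta = (folder / "consensus.faa").read_text()
    annot_path = folder / "annotations.tsv"
    annot = annot_path.read_text() if annot_path.exists() else ""
    fasta_ids = {
        line[1:].split()[0] for line in fasta.splitlines() if line.startswith(">")
    }
    for lineno, line in enumerate(annot.splitlines(), start=1):
        if lineno == 1 and line.startswith("cluster_id"):
            continue
        if not line.strip():
            continue
        cid = line.split("\t")[0]
        if cid not in fasta_ids:
            raise DatabaseError(
                f"taxon {name!r}: annotation cluster id {cid!r} not in consensus FASTA"
            )
    return name, rank, count, fasta, annot


def create_db(
    input_dir: str | Path,
    output_path: str | Path,
    min_proteomes: int = 5,
) -> tuple[Path, list[str]]:
    """Build a database archive from per-taxon folders.

    Each subfolder of ``input_dir`` supplies ``metadata.json`` (with
    taxon_name, rank, proteome_count), ``consensus.faa`` and
    ``annotations.tsv``.  Taxa with ``proteome_count < min_proteomes``
    are excluded and logged.  Returns the archive path and the excluded
    taxon names.
    """
    input_dir = Path(input_dir)
    output_path = Path(output_path)
    folders = sorted(p for p in input_dir.iterdir() if p.is_dir()) if input_dir.exists() else []
    if not folders:
        raise DatabaseError(f"no taxa found in {input_dir}")
    included: list[tuple[str, Rank, int, str, str]] = []
    excluded: list[str] = []
    for folder in folders:
        name, rank, count, fasta, annot = _read_taxon_folder(folder)
        if count >= min_proteomes:
            included.append((name, rank, count, fasta, annot))
        else:
            excluded.append(name)
            logger.info(
                "excluding %s (%s): %d proteomes < threshold %d",
                name, rank.value, count, min_proteomes,
            )
    included.sort(key=lambda item: (item[0], item[1].value))
    taken: set[str] = set()
    index_rows = ["taxon_name\trank\tproteome_count\tproteome_path\tannotation_path"]
    members: list[tuple[str, str]] = []
    for name, rank, count, fasta, annot in included:
        token = _sanitize(name, taken)
        ppath = f"proteomes/{token}.faa"
        apath = f"annotations/{token}.tsv"
        index_rows.append(f"{name}\t{rank.value}\t{count}\t{ppath}\t{apath}")
        members.append((ppath, fasta))
        members.append((apath, annot))
    output_path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(output_path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for arcname, payload in [("index.tsv", "\n".join(index_rows) + "\n")] + members:
            info = zipfile.ZipInfo(arcname, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, payload)
    return output_path, excluded


def load_index(archive_path: str | Path) -> list[TaxonIndexEntry]:
    with zipfile.ZipFile(archive_path) as zf:
        try:
            text = zf.read("index.tsv").decode()
        except KeyError as exc:
            raise DatabaseError(f"{archive_path}: missing index.tsv") from exc
    entries: list[TaxonIndexEntry] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if lineno == 1 or not line.strip():
            continue
        name, rank, count, ppath, apath = line.split("\t")
        entries.append(
            TaxonIndexEntry(
                taxon_name=name,
                rank=Rank.from_label(rank),
                proteome_count=int(count),
                proteome_path=ppath,
                annotation_path=apath,
            )
        )
    return entries


def resolve_affiliation(
    affiliation: TaxonomicAffiliation,
    index: Iterable[TaxonIndexEntry] | Mapping[tuple[str, Rank], TaxonIndexEntry],
) -> ResolutionResult:
    """Walk the lineage most-specific first and return the first index match.

    Deterministic and independent of index ordering: the lookup key is
    the exact (name, rank) pair, and the walk order is fixed by the
    lineage itself.
    """
    if isinstance(index, Mapping):
        lookup = index
    else:
        lookup = {(e.taxon_name, e.rank): e for e in index}
    for rank, name in reversed(affiliation.lineage):
        entry = lookup.get((name, rank))
        if entry is not None:
            return ResolutionResult(
                observation_id=affiliation.observation_id,
                status="resolved",
                matched_taxon=entry,
                matched_rank=rank,
            )
    return ResolutionResult(observation_id=affiliation.observation_id, status="unresolved")


def index_lookup(
    index: Iterable[TaxonIndexEntry],
) -> dict[tuple[str, Rank], TaxonIndexEntry]:
    return {(e.taxon_name, e.rank): e for e in index}


def load_taxon_record(archive_path: str | Path, entry: TaxonIndexEntry) -> TaxonRecord:
    """Extract one taxon's consensus proteome and annotations.

    Sequences and annotation rows are joined on cluster id; an
    annotation row naming an unknown cluster id is kept (with empty
    membership) and logged as a warning.
    """
    with zipfile.ZipFile(archive_path) as zf:
        names = set(zf.namelist())
        for member in (entry.proteome_path, entry.annotation_path):
            if member not in names:
                raise DatabaseError(f"{archive_path}: missing archive member {member!r}")
        fasta_text = zf.read(entry.proteome_path).decode()
        annot_text = zf.read(entry.annotation_path).decode()
    sequences: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            if current is not None:
                sequences[current] = "".join(chunks)
            current = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if current is not None:
        sequences[current] = "".join(chunks)
    members: dict[str, tuple[str, ...]] = {}
    annotations: dict[str, tuple[str, ...]] = {}
    extra: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = []
    for lineno, line in enumerate(annot_text.splitlines(), start=1):
        if not line.strip() or (lineno == 1 and line.startswith("cluster_id")):
            continue
        fields = line.split("\t")
        cid = fields[0]
        prot = tuple(p for p in fields[1].split(",") if p) if len(fields) > 1 else ()
        labels = tuple(a for a in fields[2].split(",") if a) if len(fields) > 2 else ()
        if cid not in sequences:
            logger.warning(
                "%s: annotation row for unknown cluster %r kept with empty membership",
                entry.taxon_name, cid,
            )
            extra.append((cid, (), labels))
            continue
        members[cid] = prot
        annotations[cid] = labels
    clusters = tuple(
        ProteinCluster(
            cluster_id=cid,
            consensus_sequence=seq,
            member_protein_ids=members.get(cid, (cid,)),
            annotations=annotations.get(cid, ()),
        )
        for cid, seq in sequences.items()
    ) + tuple(
        ProteinCluster(cluster_id=cid, consensus_sequence="", member_protein_ids=prot,
                       annotations=labels)
        for cid, prot, labels in extra
    )
    return TaxonRecord(
        taxon_name=entry.taxon_name,
        rank=entry.rank,
        clusters=clusters,
        proteome_count=entry.proteome_count,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_index(entries: Sequence[TaxonIndexEntry]) -> pd.DataFrame:
    """Per-rank included-taxon and proteome counts, with a total row."""
    rows = []
    by_rank: dict[Rank, list[TaxonIndexEntry]] = {}
    for e in entries:
        by_rank.setdefault(e.rank, []).append(e)
    for rank in RANK_ORDER:
        if rank in by_rank:
            group = by_rank[rank]
            rows.append(
                {
                    "rank": rank.value,
                    "included_taxa": len(group),
                    "proteomes": sum(e.proteome_count for e in group),
                }
            )
    df = pd.DataFrame(rows, columns=["rank", "included_taxa", "proteomes"])
    total = pd.DataFrame(
        [
            {
                "rank": "total",
                "included_taxa": int(df["included_taxa"].sum()) if len(df) else 0,
                "proteomes": int(df["proteomes"].sum()) if len(df) else 0,
            }
        ]
    )
    return pd.concat([df, total], ignore_index=True)


def summarize_database(archive_path: str | Path) -> pd.DataFrame:
    return summarize_index(load_index(archive_path))


def write_resolution_report(
    resolutions: Sequence[ResolutionResult], path: str | Path
) -> Path:
    path = Path(path)
    lines = ["observation_id\tstatus\tmatched_taxon\tmatched_rank"]
    for r in resolutions:
        lines.append(
            "\t".join(
                [
                    r.observation_id,
                    r.status,
                    r.matched_taxon.taxon_name if r.matched_taxon else "",
                    r.matched_rank.value if r.matched_rank else "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path
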