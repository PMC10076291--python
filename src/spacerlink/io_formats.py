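"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (scaffolds, via Biopython), TSV (MAG and viral metadata, edge
lists), GFF3 (CRISPR arrays: ``repeat_region`` parents with ``direct_repeat``
and ``spacer`` children), GraphML + SIF (networks, for Cytoscape), YAML (run
configuration), plain-text logging.

Coordinates are 0-based half-open everywhere in memory and converted to
1-based inclusive only at the GFF3 boundary. Scaffolds shorter than the
configured floor (default 2500 bp, applied uniformly to host and viral
sequences) are dropped at load.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import yaml
from Bio import SeqIO

from ._dna import VALID_CHARS
from .vh_network import RANKS, HostMAG, QualityParams, ViralElement

if TYPE_CHECKING:  # pragma: no cover
    from .crispr_detect import CrisprArray
    from .vh_network import VirusHostNetwork

logger = logging.getLogger("spacerlink")

DEFAULT_MIN_SCAFFOLD_LEN = 2500


def configure_logging(level: str = "INFO", path: str | Path | None = None) -> None:
    """Plain-text logging with level control; optional logfile."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if path is not None:
        handlers.append(logging.FileHandler(path))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(getattr(logging, level.upper()))
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending record."""


class SchemaError(ValueError):
    """A tabular input is missing required columns or has bad values."""


class GffFormatError(ValueError):
    """GFF3 input violates the expected CRISPR-array profile."""


@dataclass
class Scaffold:
    """A contiguous assembled sequence with sample provenance."""

    id: str
    seq: str
    source_sample: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"scaffold {self.id!r} has empty sequence")
        bad = set(self.seq) - VALID_CHARS
        if bad:
            raise ValueError(f"scaffold {self.id!r} has invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


def read_sequences(
    path: str | Path,
    min_len: int = DEFAULT_MIN_SCAFFOLD_LEN,
    source_sample: str = "",
    year: int = 0,
) -> list[Scaffold]:
    """Load FASTA records >= min_len bp, uppercased, order preserved.

    Characters outside {A,C,G,T,N} (other IUPAC ambiguity codes) are replaced
    with N. Duplicate record ids raise; non-FASTA text raises naming the file.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
        if head and head not in (">", ";"):
            raise FastaParseError(f"{path}: does not start with a FASTA header")
    seen: set[str] = set()
    out: list[Scaffold] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        if set(seq) - VALID_CHARS:
            seq = "".join(c if c in VALID_CHARS else "N" for c in seq)
        if len(seq) < min_len:
            continue
        out.append(Scaffold(id=rec.id, seq=seq, source_sample=source_sample, year=year))
    return out


def write_sequences(scaffolds: Iterable[Scaffold], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            fh.write(f">{sc.id}\n")
            for i in range(0, len(sc.seq), width):
                fh.write(sc.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# metadata tables
# ---------------------------------------------------------------------------

_MAG_COLUMNS = ("mag_id", "completeness", "contamination", "lineage", "site", "year")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a GTDB-style 7-rank lineage; rank prefixes (d__ etc.) stripped.

    Truncated lineages are padded with empty ranks.
    """
    parts = [p.strip() for p in text.split(";")] if text else []
    ranks = []
    for p in parts:
        if len(p) >= 3 and p[1:3] == "__":
            p = p[3:]
        ranks.append(p)
    ranks = ranks[:7]
    ranks += [""] * (7 - len(ranks))
    return tuple(ranks)


def format_lineage(lineage: Sequence[str]) -> str:
    prefixes = "dpcofgs"
    return ";".join(f"{prefixes[i]}__{v}" for i, v in enumerate(lineage))


def read_mag_table(path: str | Path) -> list[HostMAG]:
    """Parse the MAG metadata TSV (CheckM/GTDB-style columns)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in _MAG_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        mags = []
        for row in reader:
            try:
                mag = HostMAG(
                    mag_id=row["mag_id"],
                    scaffold_ids=tuple(
                        s for s in row.get("scaffold_ids", "").split(",") if s
                    ),
                    completeness=float(row["completeness"]),
                    contamination=float(row["contamination"]),
                    lineage=parse_lineage(row["lineage"]),
                    site=row["site"],
                    year=int(row["year"]),
                )
            except ValueError as e:
                raise SchemaError(f"{path}: row {row.get('mag_id')!r}: {e}") from e
            mags.append(mag)
    return mags


def write_mag_table(mags: Iterable[HostMAG], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(_MAG_COLUMNS) + ["scaffold_ids"])
        for m in mags:
            w.writerow(
                [m.mag_id, f"{m.completeness:.2f}", f"{m.contamination:.2f}",
                 format_lineage(m.lineage), m.site, m.year, ",".join(m.scaffold_ids)]
            )


_VIRAL_COLUMNS = ("viral_id", "length", "site", "year", "category")


def read_viral_table(path: str | Path) -> list[ViralElement]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in _VIRAL_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        out = []
        for row in reader:
            try:
                out.append(
                    ViralElement(
                        viral_id=row["viral_id"],
                        scaffold_id=row.get("scaffold_id", row["viral_id"]),
                        length=int(row["length"]),
                        site=row["site"],
                        year=int(row["year"]),
                        dgr_flag=row.get("dgr_flag", "0") in ("1", "true", "True"),
                        category=row["category"],
                    )
                )
            except ValueError as e:
                raise SchemaError(f"{path}: row {row.get('viral_id')!r}: {e}") from e
    return out


def write_viral_table(virals: Iterable[ViralElement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(_VIRAL_COLUMNS) + ["scaffold_id", "dgr_flag"])
        for v in virals:
            w.writerow(
                [v.viral_id, v.length, v.site, v.year, v.category,
                 v.scaffold_id, int(v.dgr_flag)]
            )


# ---------------------------------------------------------------------------
# networks (edge TSV + SIF + GraphML)
# ---------------------------------------------------------------------------


def write_network(net: "VirusHostNetwork", prefix: str | Path) -> dict[str, Path]:
    """Export a network as <prefix>.edges.tsv, <prefix>.sif, <prefix>.graphml."""
    import networkx as nx

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    edge_path = prefix.with_suffix(".edges.tsv")
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["host_id", "viral_id", "n_matches", "host_site", "viral_site"])
        for hid, vid in sorted(net.edges):
            w.writerow(
                [hid, vid, net.weights[(hid, vid)],
                 net.hosts[hid].site, net.virals[vid].site]
            )
    sif_path = prefix.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for hid, vid in sorted(net.edges):
            fh.write(f"{hid}\ttargets\t{vid}\n")
    graphml_path = prefix.with_suffix(".graphml")
    nx.write_graphml(net.to_networkx(), graphml_path)
    return {"edges": edge_path, "sif": sif_path, "graphml": graphml_path}


def read_network_edges(path: str | Path) -> list[dict]:
    """Edge rows from a network edge TSV (the write_network round-trip half)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for row in reader:
            row["n_matches"] = int(row["n_matches"])
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# GFF3 (CRISPR array profile)
# ---------------------------------------------------------------------------


@dataclass
class GffRecord:
    """One GFF3 feature line; start/end stored 0-based half-open."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)


def parse_gff3(path: str | Path) -> list[GffRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffFormatError(f"{path}:{ln}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attrd = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrd[k] = v
            records.append(
                GffRecord(
                    seqid=seqid,
                    type=ftype,
                    start=int(start) - 1,  # GFF3 is 1-based inclusive
                    end=int(end),
                    strand=strand,
                    attributes=attrd,
                )
            )
    return records


def write_arrays_gff(arrays: Iterable["CrisprArray"], path: str | Path) -> None:
    """Emit arrays as repeat_region parents with direct_repeat/spacer children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for arr in arrays:
            start, end = arr.interval
            attrs = f"ID={arr.array_id}"
            if arr.partial:
                attrs += ";partial=true"
            fh.write(
                f"{arr.scaffold_id}\tspacerlink\trepeat_region\t{start + 1}\t{end}"
                f"\t.\t+\t.\t{attrs}\n"
            )
            for i, (rs, re_) in enumerate(arr.repeats):
                fh.write(
                    f"{arr.scaffold_id}\tspacerlink\tdirect_repeat\t{rs + 1}\t{re_}"
                    f"\t.\t+\t.\tID={arr.array_id}_repeat_{i};Parent={arr.array_id}\n"
                )
            for idx, (ss, se), _seq in arr.spacers:
                fh.write(
                    f"{arr.scaffold_id}\tspacerlink\tspacer\t{ss + 1}\t{se}"
                    f"\t.\t+\t.\tID={arr.array_id}_spacer_{idx};Parent={arr.array_id}\n"
                )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def _default_match_params():
    from .spacer_match import MatchParams

    return MatchParams()


def _default_detect_params():
    from .crispr_detect import DetectParams

    return DetectParams()


def _default_provirus_params():
    from .interviral import ProvirusParams

    return ProvirusParams()


def _default_cluster_params():
    from .temporal import ClusterParams

    return ClusterParams()


def _default_chi_params():
    from .chi_analysis import ChiParams

    return ChiParams()


@dataclass
class RunConfig:
    """All tunables of a pipeline run; YAML round-trips identically."""

    min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN
    match_params: object = field(default_factory=_default_match_params)
    detect_params: object = field(default_factory=_default_detect_params)
    provirus_params: object = field(default_factory=_default_provirus_params)
    cluster_params: object = field(default_factory=_default_cluster_params)
    quality_params: QualityParams = field(default_factory=QualityParams)
    chi_params: object = field(default_factory=_default_chi_params)
    rng_seed: int = 0
    output_dir: str = "spacerlink_out"

    def __post_init__(self) -> None:
        if self.min_scaffold_len < 0:
            raise ValueError("min_scaffold_len must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .chi_analysis import ChiParams
        from .crispr_detect import DetectParams
        from .interviral import ProvirusParams
        from .spacer_match import MatchParams
        from .temporal import ClusterParams

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sections = {
            "match_params": MatchParams,
            "detect_params": DetectParams,
            "provirus_params": ProvirusParams,
            "cluster_params": ClusterParams,
            "quality_params": QualityParams,
            "chi_params": ChiParams,
        }
        kwargs = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in known:
                raise SchemaError(f"unknown config key {key!r}")
            if key in sections and isinstance(value, dict):
                section_cls = sections[key]
                valid = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise SchemaError(f"unknown {key} keys {sorted(bad)}")
                value = section_cls(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in value.items()
                    }
                )
            kwargs[key] = value
        return cls(**kwargs)
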