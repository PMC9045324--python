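"""Core data model and readers/writers for linear-replicon analysis.

This module holds the containers every other part of the toolkit works on:

* :class:`Replicon` -- a named DNA sequence with an explicit linear/circular
  topology flag.  Topology is never inferred from sequence content; giant
  linear plasmids and linear chromosomes are first-class citizens here.
* :class:`FeatureRecord` -- an annotated feature (usually a CDS) with 1-based
  inclusive coordinates and a derived functional category.
* :class:`CoverageTrack` -- dense per-base read depth over a contig.
* :class:`KeywordRules` -- the ordered keyword table used to bin CDS product
  strings into transposase / transcriptional-regulator / hypothetical / other.

Coordinates are stored 1-based inclusive on :class:`FeatureRecord` (GenBank
convention, matching what annotation pipelines print); algorithmic code that
prefers 0-based half-open intervals converts at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

LINEAR = "linear"
CIRCULAR = "circular"
TOPOLOGIES = (LINEAR, CIRCULAR)

CATEGORIES = ("transposase", "transcriptional_regulator", "hypothetical", "other")

_VALID_BASES = frozenset("ACGTN")

__all__ = [
    "LINEAR",
    "CIRCULAR",
    "CATEGORIES",
    "Replicon",
    "FeatureRecord",
    "CoverageTrack",
    "KeywordRules",
    "DEFAULT_RULES",
    "classify_feature",
    "gc_content",
    "reverse_complement",
    "load_replicons",
    "write_replicons",
    "load_features",
    "write_features_tsv",
    "read_features_tsv",
    "load_coverage",
    "write_coverage_bedgraph",
]


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class Replicon:
    """A named DNA sequence with explicit topology.

    Parameters
    ----------
    id :
        Record identifier (contig/replicon name).
    sequence :
        Uppercase DNA over the alphabet ``{A, C, G, T, N}``.
    topology :
        ``"linear"`` or ``"circular"``.  Always set explicitly; linear
        chromosomes and giant linear plasmids are the default subject here.
    """

    id: str
    sequence: str
    topology: str = LINEAR

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"replicon {self.id!r}: bad topology {self.topology!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"replicon {self.id!r}: illegal characters {sorted(bad)!r} "
                "(expected uppercase A/C/G/T/N)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated feature with 1-based inclusive coordinates.

    ``category`` is a pure function of ``product`` under a
    :class:`KeywordRules` table; use :func:`load_features` or
    :func:`classify_feature` to derive it rather than guessing.
    """

    replicon_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    strand: str  # "+" or "-"
    kind: str = "CDS"
    product: str = ""
    category: str = "other"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature on {self.replicon_id!r}: bad interval "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature on {self.replicon_id!r}: bad strand {self.strand!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"feature on {self.replicon_id!r}: bad category {self.category!r}")

    @property
    def length(self) -> int:
        """Inclusive length in bp: ``end - start + 1``."""
        return self.end - self.start + 1

    def interval0(self) -> tuple[int, int]:
        """The feature interval as 0-based half-open ``(start, end)``."""
        return self.start - 1, self.end


@dataclass(frozen=True)
class CoverageTrack:
    """Dense per-base read depth for one contig.

    ``depth[i]`` is the depth over base ``i + 1`` (1-based).  Values are
    non-negative floats; fractional depth (e.g. from normalized tracks) is
    allowed.
    """

    replicon_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.depth, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"coverage for {self.replicon_id!r}: need a non-empty 1-D track")
        if np.any(arr < 0):
            raise ValueError(f"coverage for {self.replicon_id!r}: negative depth values")
        object.__setattr__(self, "depth", arr)

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class KeywordRules:
    """Ordered, case-insensitive substring rules mapping products to categories.

    The first matching rule wins; a product matching no rule is ``other``.
    The default table operationalizes the usual annotation-table counting of
    transposases, transcriptional regulators and hypothetical proteins: the
    generic ``"regulator"`` keyword deliberately comes after the specific
    ``"transcriptional regulator"`` so both spell the same category, and any
    product containing ``"transposase"`` (IS-family, Mu-domain, ...) counts
    as a transposase.
    """

    rules: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("transposase", ("transposase",)),
        ("transcriptional_regulator", ("transcriptional regulator", "regulator")),
        ("hypothetical", ("hypothetical protein",)),
    )

    def __post_init__(self) -> None:
        for category, _ in self.rules:
            if category not in CATEGORIES:
                raise ValueError(f"keyword rule maps to unknown category {category!r}")

    def classify(self, product: str) -> str:
        text = (product or "").lower()
        for category, keywords in self.rules:
            if any(kw.lower() in text for kw in keywords):
                return category
        return "other"


DEFAULT_RULES = KeywordRules()


def classify_feature(product: str, rules: KeywordRules = DEFAULT_RULES) -> str:
    """Classify a CDS product string; total and deterministic (no errors)."""
    return rules.classify(product)


def gc_content(sequence: str) -> float:
    """G+C fraction of a DNA string, ignoring N bases entirely.

    Raises ``ValueError`` for an empty or all-N sequence, where the fraction
    is undefined.
    """
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    gc = sequence.count("G") + sequence.count("C")
    denom = len(sequence) - sequence.count("N")
    if denom == 0:
        raise ValueError("gc_content of all-N sequence is undefined")
    return gc / denom


# ---------------------------------------------------------------------------
# sequence I/O


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_id!r}: illegal sequence characters {sorted(bad)!r}"
        )
    return seq


def load_replicons(path: str | Path, format: str = "fasta") -> list[Replicon]:
    """Read replicons from FASTA or GenBank.

    GenBank records carry their own topology flag; FASTA has none, so FASTA
    records default to linear with a warning (linear replicons are the norm
    for the actinomycete assemblies this toolkit targets).
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no {format} records found")
    replicons = []
    for rec in records:
        seq = _clean_sequence(str(rec.seq), rec.id)
        if format == "genbank":
            topology = rec.annotations.get("topology", LINEAR)
            if topology not in TOPOLOGIES:
                topology = LINEAR
        else:
            warnings.warn(
                f"FASTA record {rec.id!r}: no topology in FASTA, assuming linear",
                stacklevel=2,
            )
            topology = LINEAR
        replicons.append(Replicon(id=rec.id, sequence=seq, topology=topology))
    return replicons


def write_replicons(replicons: Sequence[Replicon], path: str | Path, format: str = "fasta") -> None:
    """Write replicons as FASTA or GenBank (GenBank preserves topology)."""
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    records = []
    for rep in replicons:
        rec = SeqRecord(Seq(rep.sequence), id=rep.id, name=rep.id[:16], description="")
        if format == "genbank":
            rec.annotations["molecule_type"] = "DNA"
            rec.annotations["topology"] = rep.topology
        records.append(rec)
    SeqIO.write(records, str(path), format)


# ---------------------------------------------------------------------------
# feature I/O


def _check_bounds(feat: FeatureRecord, lengths: dict[str, int] | None) -> None:
    if lengths and feat.replicon_id in lengths and feat.end > lengths[feat.replicon_id]:
        raise ValueError(
            f"feature {feat.kind} [{feat.start},{feat.end}] on {feat.replicon_id!r} "
            f"exceeds replicon length {lengths[feat.replicon_id]}"
        )


def load_features(
    path: str | Path,
    format: str = "genbank",
    rules: KeywordRules = DEFAULT_RULES,
    replicon_lengths: dict[str, int] | None = None,
) -> list[FeatureRecord]:
    """Read annotated features from GenBank or GFF3.

    Every CDS is categorized through *rules*; non-CDS features are retained
    with their kind preserved and category ``other``.  A CDS without a
    product string warns and falls through to ``other``.
    """
    path = Path(path)
    feats: list[FeatureRecord] = []
    if format == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            for f in rec.features:
                if f.type == "source":
                    continue
                start = int(f.location.start) + 1
                end = int(f.location.end)
                strand = "-" if f.location.strand == -1 else "+"
                product = (f.qualifiers.get("product") or [""])[0]
                if f.type == "CDS" and not product:
                    warnings.warn(
                        f"CDS at [{start},{end}] on {rec.id!r} has no product; "
                        "category set to 'other'",
                        stacklevel=2,
                    )
                category = rules.classify(product) if f.type == "CDS" else "other"
                feat = FeatureRecord(
                    replicon_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    kind=f.type,
                    product=product,
                    category=category,
                )
                _check_bounds(feat, replicon_lengths or {rec.id: len(rec.seq)})
                feats.append(feat)
    elif format == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for f in db.all_features():
            if f.featuretype in ("region", "source"):
                continue
            product = (f.attributes.get("product") or [""])[0]
            if f.featuretype == "CDS" and not product:
                warnings.warn(
                    f"CDS at [{f.start},{f.end}] on {f.seqid!r} has no product; "
                    "category set to 'other'",
                    stacklevel=2,
                )
            category = rules.classify(product) if f.featuretype == "CDS" else "other"
            feat = FeatureRecord(
                replicon_id=f.seqid,
                start=int(f.start),
                end=int(f.end),
                strand="-" if f.strand == "-" else "+",
                kind=f.featuretype,
                product=product,
                category=category,
            )
            _check_bounds(feat, replicon_lengths)
            feats.append(feat)
    else:
        raise ValueError(f"unsupported format {format!r}")
    return feats


_FEATURE_COLUMNS = ("replicon_id", "start", "end", "strand", "kind", "product", "category")


def write_features_tsv(features: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write features as TSV with a commented header naming columns and version."""
    with open(path, "w") as fh:
        fh.write(f"# linrep {__version__}; columns: {', '.join(_FEATURE_COLUMNS)}\n")
        for f in features:
            fh.write(
                f"{f.replicon_id}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\t"
                f"{f.product}\t{f.category}\n"
            )


def read_features_tsv(path: str | Path) -> list[FeatureRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", names=_FEATURE_COLUMNS,
                     dtype={"product": str}, keep_default_na=False)
    return [
        FeatureRecord(
            replicon_id=row.replicon_id, start=int(row.start), end=int(row.end),
            strand=row.strand, kind=row.kind, product=row.product, category=row.category,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# coverage I/O


def load_coverage(path: str | Path, format: str = "bedgraph") -> CoverageTrack:
    """Read a per-base coverage track.

    ``bedgraph``: 0-based half-open intervals (chrom, start, end, depth),
    sorted, contiguous from 0 with no gaps or overlaps -- the first offending
    interval is reported.  ``tsv``: two columns (1-based position, depth),
    positions contiguous from 1.
    """
    path = Path(path)
    if format == "bedgraph":
        df = pd.read_csv(
            path, sep=r"\s+", comment="#",
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str},
        )
        if df.empty:
            raise ValueError(f"{path}: empty bedGraph")
        chroms = df["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(f"{path}: multiple contigs in one track: {list(chroms)!r}")
        starts = df["start"].to_numpy(int)
        ends = df["end"].to_numpy(int)
        if starts[0] != 0:
            raise ValueError(f"{path}: track must start at 0, first interval begins {starts[0]}")
        breaks = np.nonzero(starts[1:] != ends[:-1])[0]
        if breaks.size:
            i = int(breaks[0]) + 1
            word = "gap" if starts[i] > ends[i - 1] else "overlap"
            raise ValueError(
                f"{path}: {word} at interval {i} "
                f"({df.iloc[i - 1].end} -> {df.iloc[i].start})"
            )
        depth = np.repeat(df["depth"].to_numpy(float), ends - starts)
        return CoverageTrack(replicon_id=str(chroms[0]), depth=depth)
    if format == "tsv":
        df = pd.read_csv(path, sep=r"\s+", comment="#", names=["position", "depth"])
        if df.empty:
            raise ValueError(f"{path}: empty coverage TSV")
        pos = df["position"].to_numpy(int)
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            i = int(np.nonzero(pos != expected)[0][0])
            raise ValueError(f"{path}: positions must run 1..n; row {i} has {pos[i]}")
        return CoverageTrack(replicon_id=path.stem, depth=df["depth"].to_numpy(float))
    raise ValueError(f"unsupported format {format!r}")


def write_coverage_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-encoded bedGraph (0-based half-open)."""
    depth = track.depth
    change = np.nonzero(np.diff(depth))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [depth.size]])
    with open(path, "w") as fh:
        fh.write(f"# linrep {__version__}; bedGraph chrom start end depth\n")
        for s, e in zip(starts, ends):
            fh.write(f"{track.replicon_id}\t{s}\t{e}\t{depth[s]:g}\n")
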