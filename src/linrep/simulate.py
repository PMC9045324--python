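"""Seeded synthetic linear replicons with exact ground truth.

Everything downstream of assembly in this toolkit is testable without any
download by simulating the study system: high-GC (~70%) linear replicons
with planted CDS cassettes (transposases, regulators, hypotheticals),
derived plasmids carrying insertions / deletions / inversions /
translocations / substitutions, arm-deletion-plus-inverted-duplication
plasmids whose assemblies collapse to ``arm + central`` with doubled
coverage over the arm, and gel-band observations with multiplicative size
error and a small-fragment visibility cutoff.

Every generator is a pure function of its explicit inputs and seed:
rerunning with the same seed is bit-identical.  The base model is i.i.d.
with P(G or C) = gc_target -- no codon or dinucleotide structure -- which
is sufficient for digestion and anchoring statistics; see the package
methods notes for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    CoverageTrack,
    FeatureRecord,
    Replicon,
    classify_feature,
    reverse_complement,
)

__all__ = [
    "PlannedEvent",
    "AppliedEvent",
    "TruthSet",
    "SimConfig",
    "generate_replicon",
    "plant_cassettes",
    "apply_events",
    "sample_events",
    "make_inverted_repeat_plasmid",
    "simulate_coverage",
    "simulate_gel_observation",
    "run_simulation",
]

_BASES = np.array(list("ACGT"))

# product strings drawn per category, keyword-classifiable by construction
PRODUCT_TEMPLATES = {
    "transposase": (
        "IS5 family transposase",
        "IS481 family transposase",
        "Mu transposase domain-containing protein",
        "IS701 family transposase",
    ),
    "transcriptional_regulator": (
        "GntR family transcriptional regulator",
        "TetR/AcrR family transcriptional regulator",
        "MarR family transcriptional regulator",
    ),
    "hypothetical": ("hypothetical protein",),
    "other": (
        "cytochrome P450",
        "ABC transporter ATP-binding protein",
        "DNA polymerase III subunit beta",
    ),
}


@dataclass(frozen=True)
class PlannedEvent:
    """One mutation to apply to a reference replicon.

    ``position`` is 0-based on the reference: for an insertion it is the
    number of reference bases kept before the inserted material; for the
    other types it is the interval start.  ``dest`` (translocations) is the
    0-based reference insertion point of the moved segment.  An insertion
    takes its sequence from ``sequence``, from ``donor_interval`` on the
    *donor* replicon passed to :func:`apply_events`, or is sampled randomly.
    """

    type: str  # insertion | deletion | inversion | translocation | substitution
    position: int
    length: int = 0
    sequence: str | None = None
    donor_interval: tuple[int, int] | None = None
    dest: int | None = None
    alt: str | None = None


@dataclass(frozen=True)
class AppliedEvent:
    """Ground-truth record of an applied event, in reporting coordinates.

    Conventions match the rearrangement mapper: ``a_locus`` is 1-based on
    the reference (for insertions, the last reference base before the
    insertion; for deletions, the first deleted base; otherwise the interval
    start), and ``b_interval`` is 1-based inclusive on the derived sequence.
    """

    type: str
    a_locus: int
    b_interval: tuple[int, int]
    length: int


@dataclass
class TruthSet:
    """Everything needed to score downstream calls exactly."""

    features: list[FeatureRecord] = field(default_factory=list)
    events: list[AppliedEvent] = field(default_factory=list)
    substitutions: list[tuple[int, int, str, str]] = field(default_factory=list)
    arm_interval: tuple[int, int] | None = None
    central_interval: tuple[int, int] | None = None
    full_length: int | None = None
    fragments: dict[str, list[int]] = field(default_factory=dict)
    coverage_step: list[tuple[int, int, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["features"] = [asdict(f) for f in self.features]
        payload["events"] = [asdict(e) for e in self.events]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate_replicon(
    length: int,
    gc_target: float = 0.72,
    seed: int = 0,
    replicon_id: str = "sim",
) -> Replicon:
    """An i.i.d. random linear replicon with P(G or C) = *gc_target*."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc_target <= 1.0):
        raise ValueError("gc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return Replicon(
        id=replicon_id, sequence=_random_dna(rng, length, gc_target), topology="linear"
    )


def plant_cassettes(
    replicon: Replicon,
    spec: Sequence[tuple[int, int, str]],
    seed: int = 0,
    window: tuple[int, int] | None = None,
    max_tries: int = 10000,
) -> list[FeatureRecord]:
    """Plant non-overlapping CDS cassettes and return their feature records.

    *spec* is a list of ``(count, length_bp, category)`` triples.  Placement
    is uniform within *window* (0-based half-open; default the whole
    replicon).  Product strings are drawn from category-typical templates so
    keyword classification recovers the planted category exactly.  Raises if
    the cassettes cannot be placed without overlap in *max_tries* draws.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window if window else (0, replicon.length)
    placed: list[tuple[int, int]] = []
    feats: list[FeatureRecord] = []
    for count, length, category in spec:
        templates = PRODUCT_TEMPLATES[category]
        for _ in range(count):
            for _try in range(max_tries):
                start = int(rng.integers(lo, hi - length + 1))
                if all(start + length <= s or start >= e for s, e in placed):
                    break
            else:
                raise ValueError(
                    f"could not place a {length}-bp {category} cassette "
                    f"without overlap after {max_tries} tries"
                )
            placed.append((start, start + length))
            product = templates[int(rng.integers(len(templates)))]
            assert classify_feature(product) == category
            feats.append(
                FeatureRecord(
                    replicon_id=replicon.id,
                    start=start + 1,
                    end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    kind="CDS",
                    product=product,
                    category=category,
                )
            )
    feats.sort(key=lambda f: f.start)
    return feats


# ---------------------------------------------------------------------------
# rearrangement events


def _event_footprints(ev: PlannedEvent) -> list[tuple[int, int]]:
    if ev.type == "insertion":
        return [(ev.position, ev.position)]
    if ev.type == "substitution":
        return [(ev.position, ev.position + 1)]
    if ev.type == "translocation":
        return [(ev.position, ev.position + ev.length), (ev.dest, ev.dest)]
    return [(ev.position, ev.position + ev.length)]


def apply_events(
    replicon: Replicon,
    events: Sequence[PlannedEvent],
    seed: int = 0,
    donor: Replicon | None = None,
    gc_target: float = 0.72,
) -> tuple[Replicon, TruthSet]:
    """Apply a set of non-overlapping events; record exact derived coordinates.

    Total length is conserved exactly: derived length equals the original
    plus the sum of insertion lengths minus the sum of deletion lengths.
    Overlapping event footprints are an error, as is any locus outside the
    reference.
    """
    rng = np.random.default_rng(seed)
    ref = replicon.sequence
    L = len(ref)

    footprints: list[tuple[int, int, PlannedEvent]] = []
    for ev in events:
        for s, e in _event_footprints(ev):
            if not (0 <= s <= e <= L):
                raise ValueError(f"event {ev.type} at {ev.position} outside reference")
            footprints.append((s, e, ev))
    footprints.sort(key=lambda t: (t[0], t[1]))
    for (s1, e1, v1), (s2, e2, v2) in zip(footprints, footprints[1:]):
        if s2 < e1 or (s2 == s1 and v1 is not v2):
            raise ValueError(
                f"overlapping events: {v1.type}@{v1.position} and {v2.type}@{v2.position}"
            )

    # Normalize into walk items: (ref_pos, kind, event, payload_sequence).
    items: list[tuple[int, int, str, PlannedEvent, str]] = []
    for ev in events:
        if ev.type == "insertion":
            if ev.sequence is not None:
                seq = ev.sequence
            elif ev.donor_interval is not None:
                src = donor.sequence if donor is not None else ref
                seq = src[ev.donor_interval[0]: ev.donor_interval[1]]
            else:
                seq = _random_dna(rng, ev.length, gc_target)
            items.append((ev.position, 1, "insert", ev, seq))
        elif ev.type == "deletion":
            items.append((ev.position, 0, "delete", ev, ""))
        elif ev.type == "inversion":
            items.append((ev.position, 0, "invert", ev, ""))
        elif ev.type == "translocation":
            if ev.dest is None:
                raise ValueError("translocation needs a dest")
            seq = ref[ev.position: ev.position + ev.length]
            items.append((ev.position, 0, "cut", ev, ""))
            items.append((ev.dest, 1, "paste", ev, seq))
        elif ev.type == "substitution":
            alt = ev.alt
            if alt is None:
                choices = [b for b in "ACGT" if b != ref[ev.position]]
                alt = choices[int(rng.integers(3))]
            if alt == ref[ev.position]:
                raise ValueError(f"substitution at {ev.position} does not change the base")
            items.append((ev.position, 0, "substitute", ev, alt))
        else:
            raise ValueError(f"unknown event type {ev.type!r}")
    items.sort(key=lambda t: (t[0], t[1]))

    out: list[str] = []
    out_len = 0
    cur = 0
    truth = TruthSet()

    def emit(chunk: str) -> None:
        nonlocal out_len
        out.append(chunk)
        out_len += len(chunk)

    for pos, _order, kind, ev, payload in items:
        emit(ref[cur:pos])
        cur = max(cur, pos)
        if kind == "insert" or kind == "paste":
            start_b = out_len + 1
            emit(payload)
            truth.events.append(
                AppliedEvent(
                    type="insertion" if kind == "insert" else "translocation",
                    a_locus=pos if kind == "insert" else ev.position + 1,
                    b_interval=(start_b, out_len),
                    length=len(payload),
                )
            )
        elif kind == "delete":
            # record the left-aligned (canonical) locus: deleting either copy
            # of a repeated base yields the same derived sequence
            canon = pos
            while canon > 0 and ref[canon - 1] == ref[canon + ev.length - 1]:
                canon -= 1
            truth.events.append(
                AppliedEvent("deletion", canon + 1, (out_len, out_len), ev.length)
            )
            cur = pos + ev.length
        elif kind == "invert":
            start_b = out_len + 1
            emit(reverse_complement(ref[pos: pos + ev.length]))
            truth.events.append(
                AppliedEvent("inversion", pos + 1, (start_b, out_len), ev.length)
            )
            cur = pos + ev.length
        elif kind == "cut":
            cur = pos + ev.length
        elif kind == "substitute":
            truth.substitutions.append((pos + 1, out_len + 1, ref[pos], payload))
            emit(payload)
            cur = pos + 1
    emit(ref[cur:])

    derived = Replicon(
        id=f"{replicon.id}_derived", sequence="".join(out), topology="linear"
    )
    truth.events.sort(key=lambda e: e.a_locus)
    return derived, truth


def sample_events(
    ref_length: int,
    rng: np.random.Generator,
    types: Sequence[str] = ("insertion", "deletion", "inversion", "translocation"),
    n_events: int = 2,
    min_len: int = 600,
    max_len: int = 3000,
    n_substitutions: int = 0,
    margin: int = 2000,
    max_tries: int = 10000,
) -> list[PlannedEvent]:
    """Sample a non-overlapping, well-separated random event set.

    Events keep at least *margin* bp from each other and from the replicon
    ends so each one is flanked by anchorable unique sequence.
    """
    taken: list[tuple[int, int]] = []

    def claim(length: int) -> int:
        for _ in range(max_tries):
            s = int(rng.integers(margin, ref_length - margin - length))
            if all(s + length + margin <= a or s >= b + margin for a, b in taken):
                taken.append((s, s + length))
                return s
        raise ValueError("could not place events without overlap")

    events: list[PlannedEvent] = []
    for _ in range(n_events):
        etype = types[int(rng.integers(len(types)))]
        length = int(rng.integers(min_len, max_len + 1))
        if etype == "insertion":
            pos = claim(1)
            events.append(PlannedEvent("insertion", pos, length=length))
        elif etype == "translocation":
            pos = claim(length)
            # Keep the destination further away than the segment is long:
            # for shorter displacements "which block moved" is genuinely
            # ambiguous (moving X left equals moving its neighbor right).
            for _ in range(max_tries):
                d = int(rng.integers(margin, ref_length - margin - 1))
                far = d <= pos - length - margin or d >= pos + 2 * length + margin
                if far and all(
                    d + 1 + margin <= s or d >= e + margin for s, e in taken
                ):
                    taken.append((d, d + 1))
                    break
            else:
                raise ValueError("could not place a translocation destination")
            events.append(PlannedEvent("translocation", pos, length=length, dest=d))
        else:
            pos = claim(length)
            events.append(PlannedEvent(etype, pos, length=length))
    for _ in range(n_substitutions):
        pos = claim(1)
        events.append(PlannedEvent("substitution", pos))
    return events


# ---------------------------------------------------------------------------
# collapsed inverted repeat, coverage, gel


def make_inverted_repeat_plasmid(
    replicon: Replicon, arm_length: int, central_length: int
) -> tuple[Replicon, Replicon, TruthSet]:
    """Build a terminally inverted-duplicated plasmid and its collapsed form.

    The full plasmid is ``arm + central + revcomp(arm)`` (length 2R + C);
    the collapsed contig is ``arm + central`` -- what an assembler that
    cannot separate the two repeat copies emits.  Arm and central sequence
    are taken from the start of *replicon*.
    """
    R, C = arm_length, central_length
    if R <= 0:
        raise ValueError("arm length must be positive")
    if C < 0:
        raise ValueError("central length must be non-negative")
    if R + C > replicon.length:
        raise ValueError("replicon too short for requested arm + central")
    arm = replicon.sequence[:R]
    central = replicon.sequence[R: R + C]
    full = Replicon(
        id=f"{replicon.id}_full",
        sequence=arm + central + reverse_complement(arm),
        topology="linear",
    )
    collapsed = Replicon(
        id=f"{replicon.id}_collapsed", sequence=arm + central, topology="linear"
    )
    truth = TruthSet(
        arm_interval=(0, R),
        central_interval=(R, R + C),
        full_length=2 * R + C,
    )
    return full, collapsed, truth


def simulate_coverage(
    contig_length: int,
    arm_interval: tuple[int, int],
    baseline_depth: float = 40.0,
    noise: float = 0.15,
    seed: int = 0,
    replicon_id: str = "sim_collapsed",
) -> CoverageTrack:
    """Per-base depth over a collapsed contig: 2x baseline over the arm.

    Expected depth is ``2 * baseline`` inside *arm_interval* (0-based
    half-open) and ``baseline`` elsewhere; realized depth multiplies the
    expectation by ``1 + Uniform(-noise, +noise)`` independently per base.
    """
    if baseline_depth <= 0:
        raise ValueError("baseline depth must be positive")
    rng = np.random.default_rng(seed)
    expected = np.full(contig_length, baseline_depth, dtype=float)
    expected[arm_interval[0]: arm_interval[1]] *= 2.0
    depth = expected * (1.0 + rng.uniform(-noise, noise, size=contig_length))
    return CoverageTrack(replicon_id=replicon_id, depth=depth)


def simulate_gel_observation(
    fragments: Sequence[int],
    size_error: float = 0.02,
    min_visible: int = 30000,
    seed: int = 0,
    merge_within: float | None = None,
) -> list[float]:
    """Observed band sizes for a predicted fragment multiset.

    Fragments below *min_visible* are dropped (running-condition cutoff);
    surviving sizes are perturbed multiplicatively by
    ``1 + Normal(0, size_error)``.  With *merge_within* set, bands whose
    sizes lie within that relative resolution of each other co-migrate and
    are reported once at their mean.  Sorted descending.
    """
    rng = np.random.default_rng(seed)
    visible = sorted((f for f in fragments if f >= min_visible), reverse=True)
    observed = [f * (1.0 + rng.normal(0.0, size_error)) for f in visible]
    observed.sort(reverse=True)
    if merge_within is not None and observed:
        merged: list[list[float]] = [[observed[0]]]
        for o in observed[1:]:
            if abs(merged[-1][-1] - o) / o <= merge_within:
                merged[-1].append(o)
            else:
                merged.append([o])
        observed = [float(np.mean(group)) for group in merged]
    return observed


# ---------------------------------------------------------------------------
# config-driven simulation for the CLI


@dataclass
class SimConfig:
    """Fully serializable description of one simulated study scenario."""

    seed: int = 0
    length: int = 300_000
    gc_target: float = 0.72
    cassettes: list[tuple[int, int, str]] = field(
        default_factory=lambda: [
            (21, 1000, "transposase"),
            (18, 800, "transcriptional_regulator"),
            (100, 700, "hypothetical"),
        ]
    )
    n_events: int = 2
    n_substitutions: int = 8
    arm_length: int = 100_000
    central_length: int = 25_000
    baseline_depth: float = 40.0
    coverage_noise: float = 0.15
    gel_enzyme: str = "DraI"
    gel_size_error: float = 0.02
    gel_min_visible: int = 30_000

    def validate(self) -> None:
        problems = []
        for name in ("gc_target", "coverage_noise", "gel_size_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} not in [0, 1]")
        for name in ("length", "arm_length", "central_length", "gel_min_visible"):
            if getattr(self, name) < 0 or (name == "length" and self.length == 0):
                problems.append(f"{name} must be positive")
        if self.baseline_depth <= 0:
            problems.append("baseline_depth must be positive")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.cassettes = [tuple(c) for c in cfg.cassettes]
        cfg.validate()
        return cfg


def _write_gff3(features: Sequence[FeatureRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            attrs = f"ID=cds{i};product={f.product}"
            fh.write(
                f"{f.replicon_id}\tlinrep_sim\t{f.kind}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )


def run_simulation(config: SimConfig, outdir: str | Path) -> TruthSet:
    """Generate a full fixture set (FASTA, GFF3, bedGraph, bands, truth JSON)."""
    from .digest import ENZYMES, digest_replicon
    from .io import write_coverage_bedgraph, write_replicons

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(6)]

    ref = generate_replicon(config.length, config.gc_target, seeds[0], "sim_ref")
    feats = plant_cassettes(ref, config.cassettes, seed=seeds[1])
    rng = np.random.default_rng(seeds[2])
    planned = sample_events(
        config.length, rng, n_events=config.n_events,
        n_substitutions=config.n_substitutions,
    )
    derived, truth = apply_events(ref, planned, seed=seeds[3])
    full, collapsed, ir_truth = make_inverted_repeat_plasmid(
        ref, config.arm_length, config.central_length
    )
    track = simulate_coverage(
        collapsed.length, ir_truth.arm_interval, config.baseline_depth,
        config.coverage_noise, seed=seeds[4], replicon_id=collapsed.id,
    )
    enzyme = ENZYMES[config.gel_enzyme]
    frags = digest_replicon(ref, enzyme)
    bands = simulate_gel_observation(
        frags.fragments, config.gel_size_error, config.gel_min_visible, seed=seeds[5]
    )

    truth.features = feats
    truth.arm_interval = ir_truth.arm_interval
    truth.central_interval = ir_truth.central_interval
    truth.full_length = ir_truth.full_length
    truth.fragments[enzyme.name] = list(frags.fragments)
    truth.coverage_step = [
        (0, config.arm_length, 2 * config.baseline_depth),
        (config.arm_length, collapsed.length, config.baseline_depth),
    ]

    write_replicons([ref, derived, full, collapsed], outdir / "replicons.fasta", "fasta")
    write_replicons([ref], outdir / "reference.fasta", "fasta")
    write_replicons([derived], outdir / "derived.fasta", "fasta")
    _write_gff3(feats, outdir / "features.gff3")
    write_coverage_bedgraph(track, outdir / "coverage.bedgraph")
    with open(outdir / "bands.tsv", "w") as fh:
        fh.write("# observed band sizes (bp)\n")
        for b in bands:
            fh.write(f"{b:.0f}\n")
    truth.to_json(outdir / "truth.json")
    return truth
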