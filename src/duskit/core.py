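"""Domain model for site-specific tRNA dihydrouridine (D) analysis.

Dihydrouridine is introduced into the D-loop of *E. coli* tRNAs by three
site-specific flavoenzymes: DusC modifies position 16, DusB position 17 and
DusA positions 20 and 20a (canonical tRNA numbering).  This module holds the
shared vocabulary of the package:

* :class:`TRNAReference` — a tRNA sequence plus a map from 1-based sequence
  index to canonical position label ("16", "17", "20", "20a", ...).
* :class:`DSiteAnnotation` — an annotated D site with its responsible enzyme.
* :class:`ModificationProfile` — per-site D occupancy fractions, used both as
  simulator ground truth and as the quantity the pipeline estimates.
* :class:`StrainConfig` — knockout/treatment state of a strain, and
  :func:`effective_occupancy`, which maps a baseline profile through knockout
  and aerobic-paraquat sensitivity scaling.

All coordinates in files and reports are 1-based with closed intervals, to
match tRNA numbering conventions.  Canonical labels are free-text keys so
insertion positions ("20a", "20b") need no special casing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ENZYMES = ("DusA", "DusB", "DusC")
D_SITE_LABELS = ("16", "17", "20", "20a")

#: Site specificity of the three E. coli dihydrouridine synthases.
_ENZYME_BY_LABEL = {"16": "DusC", "17": "DusB", "20": "DusA", "20a": "DusA"}

#: Default wild-type occupancy assumed at every annotated D site.  In vivo
#: stoichiometries are not known precisely; 0.90 leaves headroom for both
#: decreases and noise, and is overridable everywhere it is used.
DEFAULT_BASELINE_OCCUPANCY = 0.90

#: Default aerobic-paraquat retention factors per enzyme.  These encode only
#: the qualitative ordering observed in vivo (DusA essentially insensitive to
#: paraquat, DusC most sensitive); the numbers are configuration, not claims.
DEFAULT_SENSITIVITY = {"DusA": 1.00, "DusB": 0.60, "DusC": 0.40}

_RNA_ALPHABET = frozenset("ACGU")


def enzyme_for_label(canonical_label: str) -> str:
    """Return the Dus enzyme responsible for a canonical D-site label.

    DusC modifies position 16, DusB position 17, DusA positions 20 and 20a.

    Raises
    ------
    ValueError
        If the label is not one of the known D-site positions.
    """
    try:
        return _ENZYME_BY_LABEL[str(canonical_label)]
    except KeyError:
        raise ValueError(
            f"unknown D-site label {canonical_label!r}; expected one of {D_SITE_LABELS}"
        ) from None


@dataclass(frozen=True)
class TRNAReference:
    """A tRNA reference sequence with canonical-position labels.

    Parameters
    ----------
    id : str
        Reference identifier, e.g. ``"tRNA-Gly-GCC-1"``.
    sequence : str
        RNA sequence over {A, C, G, U}.
    canonical_map : tuple of (int, str)
        Ordered pairs (1-based sequence index, canonical label).  Indices must
        be strictly increasing and within the sequence; labels unique.
    """

    id: str
    sequence: str
    canonical_map: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: sequence contains non-RNA characters {sorted(bad)}")
        last = 0
        labels: set[str] = set()
        for idx, label in self.canonical_map:
            if not (1 <= idx <= len(self.sequence)):
                raise ValueError(f"{self.id}: canonical index {idx} outside [1, {len(self.sequence)}]")
            if idx <= last:
                raise ValueError(f"{self.id}: canonical indices not strictly increasing at {idx}")
            if label in labels:
                raise ValueError(f"{self.id}: duplicate canonical label {label!r}")
            last = idx
            labels.add(label)

    def __len__(self) -> int:
        return len(self.sequence)

    def label_for_index(self, seq_index: int) -> str | None:
        for idx, label in self.canonical_map:
            if idx == seq_index:
                return label
        return None

    def index_for_label(self, label: str) -> int | None:
        for idx, lab in self.canonical_map:
            if lab == label:
                return idx
        return None


@dataclass(frozen=True)
class DSiteAnnotation:
    """An annotated dihydrouridine site on a tRNA reference."""

    trna_id: str
    seq_index: int  # 1-based
    canonical_label: str
    enzyme: str

    def __post_init__(self) -> None:
        if self.canonical_label not in D_SITE_LABELS:
            raise ValueError(
                f"{self.trna_id}: canonical label {self.canonical_label!r} is not a D site"
            )
        expected = enzyme_for_label(self.canonical_label)
        if self.enzyme != expected:
            raise ValueError(
                f"{self.trna_id} position {self.canonical_label}: enzyme {self.enzyme!r} "
                f"does not match the site-specificity rule (expected {expected})"
            )


@dataclass
class ModificationProfile:
    """Per-site D occupancy fractions keyed by (trna_id, 1-based seq_index).

    Optionally carries the responsible enzyme per site (populated by
    :meth:`ReferenceBundle.baseline_profile`) so that strain/treatment scaling
    can be applied without re-consulting the annotation table.
    """

    occupancy: dict[tuple[str, int], float] = field(default_factory=dict)
    enzymes: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, occ in self.occupancy.items():
            if not (0.0 <= occ <= 1.0):
                raise ValueError(f"occupancy {occ} at {site} outside [0, 1]")

    def get(self, trna_id: str, seq_index: int, default: float = 0.0) -> float:
        return self.occupancy.get((trna_id, seq_index), default)

    def sites(self) -> list[tuple[str, int]]:
        return sorted(self.occupancy)

    def total(self) -> float:
        """Sum of occupancies over all sites (the pool's D content in site units)."""
        return float(sum(self.occupancy.values()))


@dataclass
class StrainConfig:
    """Knockout and treatment state of a strain.

    ``enzyme_sensitivity`` maps each enzyme to the fraction of its baseline
    activity retained under aerobic paraquat treatment; it is applied only
    when ``paraquat_mM > 0`` and ``aerobic`` is true (paraquat needs oxygen to
    redox-cycle and drain NADPH).
    """

    name: str
    enzyme_active: dict[str, bool] = field(
        default_factory=lambda: {e: True for e in ENZYMES}
    )
    paraquat_mM: float = 0.0
    aerobic: bool = True
    enzyme_sensitivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY)
    )

    def __post_init__(self) -> None:
        if self.paraquat_mM < 0:
            raise ValueError("paraquat_mM must be >= 0")
        for enz, f in self.enzyme_sensitivity.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"sensitivity for {enz} must be in [0, 1], got {f}")


def strain_config(
    name: str,
    paraquat_mM: float = 0.0,
    aerobic: bool = True,
    sensitivity: dict[str, float] | None = None,
) -> StrainConfig:
    """Build a :class:`StrainConfig` from a conventional strain name.

    Recognised names: ``"WT"``, single knockouts ``"dusA"``/``"ΔdusA"`` (any
    case, optional ``Δ``/``delta`` prefix or ``_KO`` suffix) and the triple
    knockout ``"triple"``/``"dusABC"``.
    """
    key = name.replace("Δ", "").replace("delta", "").replace("_KO", "").strip()
    active = {e: True for e in ENZYMES}
    low = key.lower()
    if low in ("wt", "wild-type", "wildtype"):
        pass
    elif low in ("triple", "dusabc", "dusa,b,c"):
        active = {e: False for e in ENZYMES}
    elif low in ("dusa", "dusb", "dusc"):
        active["Dus" + low[-1].upper()] = False
    else:
        raise ValueError(f"unrecognised strain name {name!r}")
    return StrainConfig(
        name=name,
        enzyme_active=active,
        paraquat_mM=paraquat_mM,
        aerobic=aerobic,
        enzyme_sensitivity=dict(sensitivity or DEFAULT_SENSITIVITY),
    )


@dataclass
class ReferenceBundle:
    """Validated set of tRNA references plus their D-site annotations."""

    references: list[TRNAReference]
    annotations: list[DSiteAnnotation]

    def __post_init__(self) -> None:
        self._by_id = {r.id: r for r in self.references}
        if len(self._by_id) != len(self.references):
            raise ValueError("duplicate reference ids")
        for ann in self.annotations:
            ref = self._by_id.get(ann.trna_id)
            if ref is None:
                raise ValueError(f"annotation references unknown tRNA {ann.trna_id!r}")
            if not (1 <= ann.seq_index <= len(ref)):
                raise ValueError(
                    f"{ann.trna_id}: annotated index {ann.seq_index} outside the sequence"
                )
            base = ref.sequence[ann.seq_index - 1]
            if base != "U":
                raise ValueError(
                    f"{ann.trna_id} position {ann.seq_index}: annotated site is not U (found {base})"
                )

    def reference(self, trna_id: str) -> TRNAReference:
        return self._by_id[trna_id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.references]

    def annotations_for(self, trna_id: str) -> list[DSiteAnnotation]:
        return [a for a in self.annotations if a.trna_id == trna_id]

    def annotation_at(self, trna_id: str, seq_index: int) -> DSiteAnnotation | None:
        for a in self.annotations:
            if a.trna_id == trna_id and a.seq_index == seq_index:
                return a
        return None

    def baseline_profile(
        self, occupancy: float = DEFAULT_BASELINE_OCCUPANCY
    ) -> ModificationProfile:
        """Uniform wild-type occupancy at every annotated site."""
        occ = {(a.trna_id, a.seq_index): occupancy for a in self.annotations}
        enz = {(a.trna_id, a.seq_index): a.enzyme for a in self.annotations}
        return ModificationProfile(occupancy=occ, enzymes=enz)

    def total_residue_count(self, base: str) -> int:
        return sum(r.sequence.count(base) for r in self.references)


def effective_occupancy(
    baseline: ModificationProfile, strain: StrainConfig
) -> ModificationProfile:
    """Apply knockout and aerobic-paraquat scaling to a baseline profile.

    occ(site) = baseline(site) x [enzyme active ? 1 : 0]
                              x [paraquat > 0 and aerobic ? sensitivity(enzyme) : 1]

    The function is the identity for an untreated wild type, never increases
    any occupancy, and returns all zeros for the triple knockout.
    """
    treated = strain.paraquat_mM > 0 and strain.aerobic
    occ: dict[tuple[str, int], float] = {}
    for site, base in baseline.occupancy.items():
        enzyme = baseline.enzymes.get(site)
        if enzyme is None:
            raise ValueError(f"site {site} carries no enzyme assignment")
        value = base
        if not strain.enzyme_active.get(enzyme, True):
            value = 0.0
        elif treated:
            value *= strain.enzyme_sensitivity.get(enzyme, 1.0)
        occ[site] = value
    return ModificationProfile(occupancy=occ, enzymes=dict(baseline.enzymes))


def read_reference_bundle(fasta_path, annotation_tsv_path) -> ReferenceBundle:
    """Load references (FASTA) and D-site annotations (4-column TSV).

    The annotation TSV must have a header with columns
    ``trna_id, seq_index, canonical_label, enzyme``.  DNA-alphabet FASTA
    (T instead of U) is accepted and converted with a logged warning.  An
    empty annotation table is valid: the references are still returned.
    """
    references = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if "T" in seq:
            logger.warning("reference %s: converting T to U (DNA alphabet input)", rec.id)
            seq = seq.replace("T", "U")
        references.append(TRNAReference(id=rec.id, sequence=seq))

    table = pd.read_csv(annotation_tsv_path, sep="\t", dtype=str)
    required = ["trna_id", "seq_index", "canonical_label", "enzyme"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    annotations = [
        DSiteAnnotation(
            trna_id=row.trna_id,
            seq_index=int(row.seq_index),
            canonical_label=row.canonical_label,
            enzyme=row.enzyme,
        )
        for row in table.itertuples()
    ]
    # reinstate canonical labels on the references so downstream reports can
    # show them even when the FASTA came without a sidecar numbering
    by_id: dict[str, list[tuple[int, str]]] = {}
    for ann in annotations:
        by_id.setdefault(ann.trna_id, []).append((ann.seq_index, ann.canonical_label))
    references = [
        TRNAReference(
            id=r.id,
            sequence=r.sequence,
            canonical_map=tuple(sorted(by_id.get(r.id, []))),
        )
        for r in references
    ]
    return ReferenceBundle(references=references, annotations=annotations)


def write_reference_bundle(bundle: ReferenceBundle, fasta_path, annotation_tsv_path) -> None:
    """Write a bundle back to FASTA + annotation TSV (inverse of the reader)."""
    with open(fasta_path, "w") as fh:
        for ref in bundle.references:
            fh.write(f">{ref.id}\n{ref.sequence}\n")
    rows = [
        {
            "trna_id": a.trna_id,
            "seq_index": a.seq_index,
            "canonical_label": a.canonical_label,
            "enzyme": a.enzyme,
        }
        for a in bundle.annotations
    ]
    pd.DataFrame(rows, columns=["trna_id", "seq_index", "canonical_label", "enzyme"]).to_csv(
        annotation_tsv_path, sep="\t", index=False
    )
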