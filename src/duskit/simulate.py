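"""Seeded synthetic-data generators for the three assays.

The generators emulate the statistical structure the downstream analysis
assumes, so every pipeline stage is testable without any sequencing download:

* :func:`simulate_aas_library` — an AlkAnilineSeq-like read library.  The
  chemistry modelled: the saturated dihydrouridine ring opens under mild
  alkali and the strand is scissioned, and after aniline treatment a
  ligatable 5'-phosphate is deprotected at the N+1 nucleotide, so read 5'
  ends mark the position one past each modified site.  Random hydrolysis is
  mostly erased by the dephosphorylation step but leaves a small ligatable
  background; the mature 5'-monophosphate of the tRNA itself survives
  dephosphorylation incompletely and supplies spanning coverage.
* :func:`simulate_lcms_table` — nucleoside peak areas: a D signal (MS
  channel) proportional to total D content plus a small floor, and an
  adenosine signal (UV 254 nm channel) proportional to the A content of the
  tRNA pool; both carry multiplicative lognormal noise.
* :func:`simulate_mm_dataset`, :func:`simulate_a343_trace`,
  :func:`simulate_dihydrouridylation_timecourse` — Michaelis–Menten initial
  rates, NADPH-oxidation absorbance traces (Beer–Lambert at 343 nm) and
  saturating dihydrouridylation time courses.

Every generator is a pure function of its inputs and seed; a single
top-level seed spawns independent per-component streams keyed by stable
strings, so adding one generator never perturbs another's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .core import (
    DSiteAnnotation,
    ModificationProfile,
    ReferenceBundle,
    TRNAReference,
)

PROTON_UNUSED = None  # see lcms module for mass constants

#: Beer–Lambert extinction coefficient of NAD(P)H at 343 nm, mM^-1 cm^-1.
EPSILON_343_MM = 6.21

#: Default incubation time points of the dihydrouridylation assay, minutes.
DEFAULT_TIMEPOINTS_MIN = (0.0, 1.0, 5.0, 15.0, 20.0, 60.0)

#: NADPH-oxidase Michaelis–Menten presets per enzyme.  DusA carries the
#: measured kcat/Km; DusB oxidises NADPH sluggishly (kcat ~0.011 s^-1, Km not
#: separable in practice — 50 uM is a placeholder within the plausible
#: range); DusC has no detectable oxidase activity, modelled as a rate close
#: to zero so that fits flag it rather than report a number.
DUS_MM_PRESETS: dict[str, dict[str, float]] = {
    "DusA": {"kcat": 0.48, "km": 17.0},
    "DusB": {"kcat": 0.011, "km": 50.0},
    "DusC": {"kcat": 0.0005, "km": 50.0},
}

#: Dihydrouridylation time-course presets (k per min, plateau in relative D
#: units).  Chosen to reproduce the qualitative kinetics: DusA saturates
#: within ~1 min, DusB signals appear after ~5 min, DusC only after ~20 min.
DUS_TIMECOURSE_PRESETS: dict[str, tuple[float, float]] = {
    "DusA": (3.0, 1.0),
    "DusB": (0.05, 0.9),
    "DusC": (0.003, 0.8),
}


def stream(seed: int, key: str) -> np.random.Generator:
    """Independent random stream derived from (seed, stable string key)."""
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    salt = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, salt]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise factor with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class AASLibraryParams:
    """Parameters of the AlkAnilineSeq library simulator.

    alk_cleavage_prob is the probability that a D ring is opened and the
    strand scissioned, conditional on the site being modified; the per-site
    break probability is occupancy x alk_cleavage_prob.
    background_break_rate is the per-internucleotide probability of a
    residual ligatable background break.  terminal_ligatable_rate is the
    probability that a molecule's intact 5' terminus remains ligatable
    (residual mature 5'-monophosphate escaping dephosphorylation); it is what
    supplies read-through coverage in otherwise unbroken molecules.
    """

    molecules_per_trna: int = 2000
    alk_cleavage_prob: float = 0.10
    background_break_rate: float = 1e-3
    terminal_ligatable_rate: float = 0.10
    read_len: int = 50
    min_fragment_len: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alk_cleavage_prob", "background_break_rate", "terminal_ligatable_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not (self.read_len >= self.min_fragment_len >= 1):
            raise ValueError("require read_len >= min_fragment_len >= 1")
        if self.molecules_per_trna < 0:
            raise ValueError("molecules_per_trna must be >= 0")


@dataclass
class LcmsSimParams:
    """Noise model for nucleoside peak-area tables.

    The D channel receives a floor equal to ``noise_floor_frac`` of the
    reference wild-type D signal (``reference_occupancy`` at every annotated
    site), emulating the marginal signal seen even in Dus-null samples.
    """

    scale: float = 1000.0
    noise_cv: float = 0.05
    noise_floor_frac: float = 0.003
    reference_occupancy: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.noise_floor_frac < 0:
            raise ValueError("noise_cv and noise_floor_frac must be >= 0")


@dataclass
class KineticsSimParams:
    """Michaelis–Menten / time-course simulation parameters (uM, s, min)."""

    kcat: float = 0.48
    km: float = 17.0
    enzyme_conc: float = 1.0
    substrate_grid: tuple[float, ...] = (2.0, 5.0, 10.0, 17.0, 30.0, 60.0, 120.0, 240.0)
    reps: int = 3
    noise_cv: float = 0.05
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kcat, self.km, self.enzyme_conc) <= 0:
            raise ValueError("kcat, Km and enzyme_conc must be > 0")


# ---------------------------------------------------------------------------
# reference fixture builder
# ---------------------------------------------------------------------------

_FIXTURE_LEN = 76
_MIN_EDIT_DISTANCE = 5


def _canonical_map_76(has_20a: bool) -> tuple[tuple[int, str], ...]:
    labels = []
    for i in range(1, _FIXTURE_LEN + 1):
        if not has_20a:
            labels.append((i, str(i)))
        elif i <= 20:
            labels.append((i, str(i)))
        elif i == 21:
            labels.append((i, "20a"))
        else:
            labels.append((i, str(i - 1)))
    return tuple(labels)


def build_fixture_references(n_trnas: int, seed: int = 0) -> ReferenceBundle:
    """Deterministic bundle of tRNA-like 76-nt references with D-site annotations.

    Every tRNA carries annotated D sites at canonical positions 16 and 17;
    about half additionally at 20 and about a third at 20a.  Sequences are
    drawn uniformly over {A,C,G,U} with U forced at annotated indices, and
    rejected until every pair of references differs by edit distance >= 5 so
    the mapper can place reads unambiguously.
    """
    if n_trnas < 1:
        raise ValueError("n_trnas must be >= 1")
    rng = stream(seed, "fixture-references")
    bases = np.array(list("ACGU"))
    references: list[TRNAReference] = []
    annotations: list[DSiteAnnotation] = []
    accepted: list[str] = []
    for k in range(n_trnas):
        has_20 = rng.random() < 0.5
        has_20a = rng.random() < 1.0 / 3.0
        forced_u = [16, 17]
        if has_20:
            forced_u.append(20)
        if has_20a:
            forced_u.append(21)  # sequence index of canonical 20a
        for _ in range(1000):
            seq_arr = rng.choice(bases, size=_FIXTURE_LEN)
            for idx in forced_u:
                seq_arr[idx - 1] = "U"
            seq = "".join(seq_arr)
            if all(
                edlib.align(seq, other)["editDistance"] >= _MIN_EDIT_DISTANCE
                for other in accepted
            ):
                break
        else:  # pragma: no cover - rejection essentially never exhausts
            raise RuntimeError("could not generate sufficiently distinct references")
        accepted.append(seq)
        trna_id = f"tRNA-syn-{k + 1:02d}"
        references.append(
            TRNAReference(id=trna_id, sequence=seq, canonical_map=_canonical_map_76(has_20a))
        )
        annotations.append(DSiteAnnotation(trna_id, 16, "16", "DusC"))
        annotations.append(DSiteAnnotation(trna_id, 17, "17", "DusB"))
        if has_20:
            annotations.append(DSiteAnnotation(trna_id, 20, "20", "DusA"))
        if has_20a:
            annotations.append(DSiteAnnotation(trna_id, 21, "20a", "DusA"))
    return ReferenceBundle(references=references, annotations=annotations)


# ---------------------------------------------------------------------------
# AlkAnilineSeq library simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str


def simulate_aas_library(
    bundle: ReferenceBundle,
    profile: ModificationProfile,
    params: AASLibraryParams,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate an AlkAnilineSeq read library from a modification profile.

    Per simulated molecule: each annotated D site at index *i* breaks with
    probability occupancy(i) x alk_cleavage_prob, creating a ligatable 5' end
    at *i*+1 (the N+1 rule); each internucleotide bond independently breaks
    with probability background_break_rate (also ligatable); the intact 5'
    terminus is ligatable with probability terminal_ligatable_rate.  Each
    ligatable fragment of length >= min_fragment_len yields one read: the
    reference substring from its 5' end, truncated at read_len or at the next
    break.

    Returns the reads plus a truth table recording each read's origin
    (``trna_id``, 1-based 5' index, cause in {d_cleavage, background,
    terminus}).
    """
    for trna_id, idx in profile.occupancy:
        if bundle.annotation_at(trna_id, idx) is None:
            raise ValueError(f"profile site ({trna_id}, {idx}) absent from bundle annotations")

    reads: list[SimulatedRead] = []
    truth_rows: list[tuple[str, str, int, str]] = []
    counter = 0
    for ref in bundle.references:
        rng = stream(params.seed, f"aas-library:{ref.id}")
        L = len(ref)
        M = params.molecules_per_trna
        if M == 0:
            continue
        # bond j (1..L-1) sits between positions j and j+1; a break at bond j
        # deprotects a 5'-phosphate at position j+1
        bg_breaks = rng.random((M, L - 1)) < params.background_break_rate
        d_breaks = np.zeros_like(bg_breaks)
        for ann in bundle.annotations_for(ref.id):
            s = ann.seq_index
            if s >= L:
                continue  # no bond downstream of the 3'-terminal residue
            p = profile.get(ref.id, s) * params.alk_cleavage_prob
            if p > 0:
                d_breaks[:, s - 1] |= rng.random(M) < p
        terminal = rng.random(M) < params.terminal_ligatable_rate
        breaks = bg_breaks | d_breaks
        active = np.flatnonzero(breaks.any(axis=1) | terminal)
        for m in active:
            bond_idx = np.flatnonzero(breaks[m]) + 1  # 1-based bond numbers
            starts: list[tuple[int, str]] = []
            if terminal[m]:
                starts.append((1, "terminus"))
            for j in bond_idx:
                cause = "d_cleavage" if d_breaks[m, j - 1] else "background"
                starts.append((int(j) + 1, cause))
            for start, cause in starts:
                nxt = bond_idx[bond_idx >= start]
                frag_end = int(nxt[0]) if nxt.size else L
                frag_len = frag_end - start + 1
                if frag_len < params.min_fragment_len:
                    continue
                read_len = min(params.read_len, frag_len)
                seq = ref.sequence[start - 1 : start - 1 + read_len]
                counter += 1
                read_id = f"read{counter:07d}"
                reads.append(SimulatedRead(read_id=read_id, sequence=seq))
                truth_rows.append((read_id, ref.id, start, cause))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "trna_id", "start_index", "cause"])
    return reads, truth


def write_fastq(reads: list[SimulatedRead], path, quality_char: str = "I") -> None:
    """Write simulated reads as a 4-line-per-record FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{quality_char * len(read.sequence)}\n")


# ---------------------------------------------------------------------------
# LC-MS nucleoside table simulator
# ---------------------------------------------------------------------------

NUCLEOSIDE_COLUMNS = ["sample", "analyte", "channel", "area"]


def simulate_lcms_table(
    bundle: ReferenceBundle,
    profile: ModificationProfile,
    sample_name: str,
    params: LcmsSimParams,
) -> pd.DataFrame:
    """One sample's nucleoside peak areas: D by MS and adenosine by UV 254 nm.

    D_ms_area = scale x (sum of site occupancies) x noise + floor, with
    floor = noise_floor_frac x scale x (reference_occupancy x n annotated
    sites).  A_uv_area = scale x (total A residues in the tRNA pool) x noise.
    """
    rng = stream(params.seed, f"lcms:{sample_name}")
    d_signal = params.scale * profile.total() * _lognormal_factor(rng, params.noise_cv)
    floor = (
        params.noise_floor_frac
        * params.scale
        * params.reference_occupancy
        * len(bundle.annotations)
    )
    a_signal = (
        params.scale
        * bundle.total_residue_count("A")
        * _lognormal_factor(rng, params.noise_cv)
    )
    return pd.DataFrame(
        [
            {"sample": sample_name, "analyte": "D", "channel": "MS", "area": float(d_signal + floor)},
            {"sample": sample_name, "analyte": "A", "channel": "UV254", "area": float(a_signal)},
        ],
        columns=NUCLEOSIDE_COLUMNS,
    )


def simulate_lcms_replicates(
    bundle: ReferenceBundle,
    profile: ModificationProfile,
    base_name: str,
    n_replicates: int,
    params: LcmsSimParams,
) -> pd.DataFrame:
    """Stack ``n_replicates`` samples named ``{base_name}_r1`` ... into one table."""
    tables = [
        simulate_lcms_table(bundle, profile, f"{base_name}_r{i + 1}", params)
        for i in range(n_replicates)
    ]
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# kinetics simulators
# ---------------------------------------------------------------------------


def simulate_mm_dataset(params: KineticsSimParams) -> pd.DataFrame:
    """Initial-rate table (S_uM, v_uM_per_s, rep) from Michaelis–Menten truth.

    v = kcat x E x S / (Km + S), scaled by multiplicative lognormal noise.
    """
    rng = stream(params.seed, "mm-dataset")
    rows = []
    for rep in range(1, params.reps + 1):
        for s in params.substrate_grid:
            v = params.kcat * params.enzyme_conc * s / (params.km + s)
            v *= _lognormal_factor(rng, params.noise_cv)
            rows.append({"S_uM": float(s), "v_uM_per_s": float(v), "rep": rep})
    return pd.DataFrame(rows, columns=["S_uM", "v_uM_per_s", "rep"])


def simulate_a343_trace(
    rate_uM_per_s: float,
    A0: float = 1.0,
    duration_s: float = 60.0,
    dt_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """NAD(P)H-oxidation absorbance trace at 343 nm.

    A(t) = max(0, A0 - eps343 x rate/1000 x path x t) + Gaussian noise, with
    eps343 = 6.21 mM^-1 cm^-1 and a 1-cm path; the rate is in uM/s (hence the
    /1000 to mM/s).  Columns: t_s, A343 (absorbance units).
    """
    if A0 <= 0:
        raise ValueError("A0 must be > 0")
    rng = stream(seed, "a343-trace")
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    a = np.maximum(0.0, A0 - EPSILON_343_MM * (rate_uM_per_s / 1000.0) * t)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.shape)
    return pd.DataFrame({"t_s": t, "A343": a})


def simulate_dihydrouridylation_timecourse(
    k_per_min: float,
    plateau: float,
    params: KineticsSimParams,
) -> pd.DataFrame:
    """Saturating dihydrouridylation time course D(t) = plateau x (1 - e^-kt).

    Sampled at ``params.timepoints`` (minutes) with multiplicative lognormal
    noise of CV ``params.noise_cv``.  Columns: t_min, D_level.
    """
    if k_per_min < 0 or plateau < 0:
        raise ValueError("k_per_min and plateau must be >= 0")
    rng = stream(params.seed, f"timecourse:{k_per_min}:{plateau}")
    rows = []
    for t in params.timepoints:
        d = plateau * (1.0 - np.exp(-k_per_min * t))
        d *= _lognormal_factor(rng, params.noise_cv)
        rows.append({"t_min": float(t), "D_level": float(d)})
    return pd.DataFrame(rows, columns=["t_min", "D_level"])
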