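"""Amphipathic-helix sequence scanning.

Sliding-window computation of mean hydrophobicity ⟨H⟩, hydrophobic moment
⟨μH⟩, residue-class counts and net charge, in the convention of the
HELIQUEST web server, plus a configurable ALPS-like (amphipathic
lipid-packing sensor) classifier.

The hydrophobic moment of a window of N residues with hydrophobicities
H_0 … H_{N-1} placed on an ideal α-helix (100° per residue) is

    μH = (1/N) · sqrt[ (Σ H_n sin nδ)² + (Σ H_n cos nδ)² ],   δ = 100°

i.e. the per-residue magnitude of the vector sum of residue
hydrophobicities around the helical wheel. A large μH with moderate ⟨H⟩
indicates segregated hydrophobic and polar faces — an amphipathic helix.
ALPS motifs are amphipathic helices whose polar face is dominated by
small residues (Ser/Thr/Gly) rather than charged ones; they sense loosely
packed, curved membranes and are screened here by thresholds on the
window properties.

Residue positions are 1-based and inclusive throughout, matching the
"aa 36–60" style used in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "FAUCHERE_PLISKA",
    "LARGE_HYDROPHOBIC",
    "SMALL_POLAR_STG",
    "HelixWindow",
    "AlpsCriteria",
    "window_properties",
    "scan_sequence",
    "region_properties",
    "classify_alps_like",
    "read_fasta",
    "load_bundled_tpd52",
    "scan_to_records",
]

#: Fauchère–Pliška (1983) octanol/water side-chain transfer scale,
#: the default hydrophobicity scale of the HELIQUEST server.
FAUCHERE_PLISKA: Mapping[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": -0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Large hydrophobic residues as counted in lipid-droplet-binding
#: amphipathic-helix analyses.
LARGE_HYDROPHOBIC = frozenset("FILMWY")

#: Small polar / helix-breaking residues enriched on ALPS polar faces.
SMALL_POLAR_STG = frozenset("STG")

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")

#: Angular step between consecutive residues on an ideal α-helix.
DELTA_DEGREES = 100.0


@dataclass(frozen=True)
class HelixWindow:
    """Properties of one sequence window (1-based inclusive positions)."""

    start: int
    end: int
    sequence: str
    mean_H: float
    mu_H: float
    n_large_hydrophobic: int
    n_STG: int
    net_charge: int
    alps_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlpsCriteria:
    """Thresholds for the ALPS-like verdict.

    ``max_n_STG`` is the count criterion reported for TPD52-family motifs
    (S+T+G not exceeding the bound). The remaining bounds are
    non-normative defaults for the screen and are freely configurable:
    ALPS helices are amphipathic (μH bound), weakly charged (|z| bound)
    and carry enough large hydrophobic residues to insert into packing
    defects.
    """

    max_n_STG: int | None = 6
    min_mu_H: float | None = 0.4
    max_abs_net_charge: int | None = 2
    min_n_large_hydrophobic: int | None = 3
    min_mean_H: float | None = None
    max_mean_H: float | None = None

    def as_dict(self) -> dict[str, object]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_sequence(seq: str, scale: Mapping[str, float]) -> str:
    seq = seq.upper()
    unknown = sorted({c for c in seq if c not in scale})
    if unknown:
        raise ValueError(
            f"residues {unknown} have no hydrophobicity value; extend the "
            "scale mapping to scan non-standard residues"
        )
    return seq


def window_properties(
    sequence: str,
    scale: Mapping[str, float] = FAUCHERE_PLISKA,
    start: int = 1,
) -> HelixWindow:
    """Compute ⟨H⟩, μH, residue-class counts and net charge for a window.

    Parameters
    ----------
    sequence:
        Window residues (one-letter code, any case).
    scale:
        Residue → hydrophobicity mapping; every residue in ``sequence``
        must be present.
    start:
        1-based position of the first residue in the parent sequence
        (used only to label the window).
    """
    seq = _check_sequence(sequence, scale)
    if not seq:
        raise ValueError("empty window")
    n = len(seq)
    hs = [scale[c] for c in seq]
    delta = math.radians(DELTA_DEGREES)
    s = sum(h * math.sin(i * delta) for i, h in enumerate(hs))
    c = sum(h * math.cos(i * delta) for i, h in enumerate(hs))
    return HelixWindow(
        start=start,
        end=start + n - 1,
        sequence=seq,
        mean_H=sum(hs) / n,
        mu_H=math.hypot(s, c) / n,
        n_large_hydrophobic=sum(r in LARGE_HYDROPHOBIC for r in seq),
        n_STG=sum(r in SMALL_POLAR_STG for r in seq),
        net_charge=sum(r in _POSITIVE for r in seq) - sum(r in _NEGATIVE for r in seq),
    )


def scan_sequence(
    sequence: str,
    window_length: int = 18,
    step: int = 1,
    scale: Mapping[str, float] = FAUCHERE_PLISKA,
) -> list[HelixWindow]:
    """Slide a fixed-length window along a sequence.

    Returns one :class:`HelixWindow` per position; a sequence shorter
    than ``window_length`` yields an empty list. With step 1 a sequence
    of length L yields max(0, L − W + 1) windows.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = _check_sequence(sequence, scale)
    if not seq:
        raise ValueError("empty sequence")
    out = []
    for i in range(0, len(seq) - window_length + 1, step):
        out.append(window_properties(seq[i : i + window_length], scale, start=i + 1))
    return out


def region_properties(
    sequence: str,
    start: int,
    end: int,
    scale: Mapping[str, float] = FAUCHERE_PLISKA,
) -> HelixWindow:
    """Properties of an explicit residue range (1-based, inclusive).

    Helices reported in the literature have varying lengths, so region
    queries are provided separately from the fixed-length sliding scan.
    """
    seq = _check_sequence(sequence, scale)
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(
            f"region {start}-{end} outside sequence of length {len(seq)}"
        )
    return window_properties(seq[start - 1 : end], scale, start=start)


def classify_alps_like(
    window: HelixWindow, criteria: AlpsCriteria | None = None
) -> HelixWindow:
    """Evaluate ALPS-like criteria; returns the window with flags filled.

    Each configured criterion yields a named pass/fail flag plus an
    ``overall`` flag that is true only when every criterion passes. An
    all-``None`` criteria set is rejected: no vacuous verdicts.
    """
    criteria = criteria if criteria is not None else AlpsCriteria()
    active = criteria.as_dict()
    if not active:
        raise ValueError("no ALPS criteria configured")
    flags: dict[str, bool] = {}
    if criteria.max_n_STG is not None:
        flags["n_STG"] = window.n_STG <= criteria.max_n_STG
    if criteria.min_mu_H is not None:
        flags["mu_H"] = window.mu_H >= criteria.min_mu_H
    if criteria.max_abs_net_charge is not None:
        flags["net_charge"] = abs(window.net_charge) <= criteria.max_abs_net_charge
    if criteria.min_n_large_hydrophobic is not None:
        flags["large_hydrophobic"] = (
            window.n_large_hydrophobic >= criteria.min_n_large_hydrophobic
        )
    if criteria.min_mean_H is not None:
        flags["mean_H_min"] = window.mean_H >= criteria.min_mean_H
    if criteria.max_mean_H is not None:
        flags["mean_H_max"] = window.mean_H <= criteria.max_mean_H
    flags["overall"] = all(flags.values())
    return HelixWindow(
        start=window.start,
        end=window.end,
        sequence=window.sequence,
        mean_H=window.mean_H,
        mu_H=window.mu_H,
        n_large_hydrophobic=window.n_large_hydrophobic,
        n_STG=window.n_STG,
        net_charge=window.net_charge,
        alps_flags=flags,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def load_bundled_tpd52() -> str:
    """Return the bundled human TPD52 (184 aa) sequence.

    The bundled record is a synthetic best-effort reconstruction written
    without database access; its middle region (≈ residues 94–140) is
    uncertain. Prefer supplying the authoritative record fetched from
    NCBI (NM_005079.3 CDS translation) when reproducing published counts.
    """
    ref = resources.files("dropletkit.data").joinpath(
        "tpd52_human_184aa_synthetic.fasta"
    )
    with resources.as_file(ref) as path:
        return next(iter(read_fasta(path).values()))


def scan_to_records(windows: Iterable[HelixWindow]) -> list[dict]:
    """Flatten windows to plain dicts (one row per window) for CSV output."""
    rows = []
    for w in windows:
        row = {
            "start": w.start,
            "end": w.end,
            "sequence": w.sequence,
            "mean_H": w.mean_H,
            "mu_H": w.mu_H,
            "n_large_hydrophobic": w.n_large_hydrophobic,
            "n_STG": w.n_STG,
            "net_charge": w.net_charge,
        }
        for name, ok in w.alps_flags.items():
            row[f"alps_{name}"] = ok
        rows.append(row)
    return rows
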