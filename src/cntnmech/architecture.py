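"""Modular domain architecture of a multidomain adhesion protein.

CNTN4's ectodomain is a chain of six immunoglobulin C2-type (IgC2)
modules followed by four fibronectin type III (FnIII) modules.  Under
uniaxial tension an FnIII module unfolds completely, releasing its whole
sequence into the stretched chain; an IgC2 module is clamped by an
internal disulfide bridge, so only the residues outside the Cys-Cys
loop can unravel.  The expected contour-length gain of one unfolding
event is therefore

    FnIII :  n_res * l_aa - d_fold
    IgC2  : (n_res - n_protected) * l_aa - d_fold

where ``l_aa`` is the contour length contributed per residue
(0.36-0.40 nm/aa) and ``d_fold`` is the folded N-to-C span that the
module already contributed before unfolding.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "DomainSpec",
    "ProteinArchitecture",
    "ArchitectureError",
    "load_architecture",
    "cntn4_architecture",
    "predicted_unfolding_length",
]


class ArchitectureError(ValueError):
    """Malformed or physically inconsistent domain table."""


@dataclasses.dataclass(frozen=True)
class DomainSpec:
    """One module of the chain.

    Attributes
    ----------
    name : domain label, e.g. ``"FnIII_2"``.
    dclass : ``"IgC2"`` or ``"FnIII"``.
    n_res : total residue count of the module.
    n_protected : residues inside the disulfide bridge (0 for FnIII).
    linker_after : free residues linking this module to the next.
    d_fold : folded N-to-C span in nm, subtracted from the stretched
        contour when the module unfolds.
    """

    name: str
    dclass: str
    n_res: int
    n_protected: int
    linker_after: int
    d_fold: float

    def __post_init__(self) -> None:
        if self.dclass not in ("IgC2", "FnIII"):
            raise ArchitectureError(f"{self.name}: unknown domain class {self.dclass!r}")
        if min(self.n_res, self.n_protected, self.linker_after) < 0:
            raise ArchitectureError(f"{self.name}: counts must be non-negative")
        if self.n_protected > self.n_res:
            raise ArchitectureError(
                f"{self.name}: n_protected={self.n_protected} exceeds n_res={self.n_res}"
            )
        if self.dclass == "FnIII" and self.n_protected != 0:
            raise ArchitectureError(f"{self.name}: FnIII modules carry no disulfide clamp")
        if self.d_fold < 0:
            raise ArchitectureError(f"{self.name}: d_fold must be non-negative")

    @property
    def n_extensible(self) -> int:
        """Residues that can be pulled out of the fold."""
        return self.n_res - self.n_protected


@dataclasses.dataclass(frozen=True)
class ProteinArchitecture:
    """Ordered module list plus the contour gain per residue ``l_aa`` (nm/aa)."""

    domains: tuple[DomainSpec, ...]
    l_aa: float = 0.38

    def __post_init__(self) -> None:
        if not self.domains:
            raise ArchitectureError("architecture must contain at least one domain")
        if not (0.0 < self.l_aa < 1.0):
            raise ArchitectureError(f"l_aa must lie in (0, 1) nm/aa, got {self.l_aa}")

    def __len__(self) -> int:
        return len(self.domains)

    def by_class(self, dclass: str) -> tuple[DomainSpec, ...]:
        return tuple(d for d in self.domains if d.dclass == dclass)

    def predicted_lengths(self) -> dict[str, float]:
        """Predicted unfolding length (nm) for every module."""
        return {d.name: predicted_unfolding_length(d, self.l_aa) for d in self.domains}

    def folded_contour_length(self) -> float:
        """Contour length (nm) of the fully folded chain: folded module
        spans plus interdomain linkers."""
        return sum(d.d_fold + d.linker_after * self.l_aa for d in self.domains)


def predicted_unfolding_length(d: DomainSpec, l_aa: float) -> float:
    """Expected contour-length increment (nm) released by one unfolding.

    The stretched contour of the extensible residues minus the folded
    span the module occupied before the event; floored at zero (a fully
    clamped module cannot lengthen the chain).
    """
    if not (0.0 < l_aa < 1.0):
        raise ArchitectureError(f"l_aa must lie in (0, 1) nm/aa, got {l_aa}")
    return max(0.0, d.n_extensible * l_aa - d.d_fold)


_COLUMNS = ("name", "dclass", "n_res", "n_protected", "linker_after", "d_fold")


def _parse_rows(lines: Iterable[str], origin: str) -> list[DomainSpec]:
    header: list[str] | None = None
    specs: list[DomainSpec] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            if tuple(header) != _COLUMNS:
                raise ArchitectureError(
                    f"{origin}:{lineno}: expected columns {_COLUMNS}, got {tuple(header)}"
                )
            continue
        if len(fields) != len(_COLUMNS):
            raise ArchitectureError(
                f"{origin}:{lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}"
            )
        try:
            spec = DomainSpec(
                name=fields[0],
                dclass=fields[1],
                n_res=int(fields[2]),
                n_protected=int(fields[3]),
                linker_after=int(fields[4]),
                d_fold=float(fields[5]),
            )
        except (ValueError, ArchitectureError) as exc:
            raise ArchitectureError(f"{origin}:{lineno}: {exc}") from exc
        specs.append(spec)
    if not specs:
        raise ArchitectureError(f"{origin}: no domain rows found")
    return specs


def load_architecture(config_path: str | Path, l_aa: float = 0.38) -> ProteinArchitecture:
    """Read a tab-separated domain table and validate every row.

    The table has a one-line header ``name dclass n_res n_protected
    linker_after d_fold``; ``#`` lines are comments.  Errors name the
    offending row.
    """
    path = Path(config_path)
    with path.open() as fh:
        specs = _parse_rows(fh, str(path))
    return ProteinArchitecture(tuple(specs), l_aa=l_aa)


def cntn4_architecture(l_aa: float = 0.38) -> ProteinArchitecture:
    """The packaged CNTN4 table (6 IgC2 + 4 FnIII).

    Residue partitions are synthetic placeholders consistent with the
    published per-class stretched-length ranges; see the data file
    header for provenance.
    """
    ref = importlib.resources.files("cntnmech.data") / "cntn4_synthetic_architecture.tsv"
    specs = _parse_rows(ref.read_text().splitlines(), ref.name)
    return ProteinArchitecture(tuple(specs), l_aa=l_aa)
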