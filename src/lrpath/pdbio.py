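"""Fixed-column PDB reading and writing.

Only ATOM/TER/END records are handled; one site per ATOM record (or per
C-alpha when ``ca_only`` is set).  Chains map to structural domains via an
explicit ``chain_to_domain`` mapping.  On output the B-factor column is
repurposed to carry a per-site scalar (e.g. the bias-force magnitude) for
visualization in standard tooling; 0-based site indices are used
internally and 1-based serials only at the PDB boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .topology import Site, SiteModel
from .trajectory import Frame


class PDBFormatError(ValueError):
    """Raised for malformed fixed-column PDB records."""


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no usable ATOM records."""


def read_pdb(
    path: str | Path,
    *,
    ca_only: bool = False,
    chain_to_domain: Mapping[str, str] | None = None,
) -> tuple[SiteModel, Frame]:
    """Parse a PDB file into a SiteModel and a coordinate Frame.

    Parameters
    ----------
    path
        PDB file with fixed-column ATOM records.
    ca_only
        Keep only atoms named ``CA``.
    chain_to_domain
        Optional chain-id -> domain-label mapping; unmapped chains keep
        their chain id as the domain label.

    Returns
    -------
    (SiteModel, Frame)
        Coordinates are in angstroms.
    """
    path = Path(path)
    sites: list[Site] = []
    coords: list[tuple[float, float, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(
                    f"{path}:{lineno}: ATOM record shorter than coordinate "
                    f"columns (needs 54 characters)"
                )
            name = line[12:16].strip()
            if ca_only and name != "CA":
                continue
            chain = line[21].strip() or "A"
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(
                    f"{path}:{lineno}: malformed coordinate columns 31-54"
                ) from exc
            domain = chain
            if chain_to_domain is not None:
                domain = chain_to_domain.get(chain, chain)
            sites.append(
                Site(site_id=len(sites), name=name, domain=domain)
            )
            coords.append((x, y, z))
    if not sites:
        raise EmptyStructureError(f"{path}: no ATOM records parsed")
    return SiteModel(sites), Frame(np.asarray(coords, dtype=float))


def write_pdb(
    topology: SiteModel,
    frame: Frame,
    path: str | Path,
    *,
    bfactors: Sequence[float] | np.ndarray | None = None,
) -> None:
    """Write a structure as fixed-column ATOM records (8.3 coordinates).

    ``bfactors`` fills the B-factor column (default 0.00); the occupancy
    column is written as 1.00.  Domains longer than one character are
    truncated to their first character for the chain-id column.
    """
    path = Path(path)
    if frame.n_sites != topology.n_sites:
        raise ValueError("frame size does not match topology")
    if bfactors is None:
        b = np.zeros(topology.n_sites)
    else:
        b = np.asarray(bfactors, dtype=float)
        if b.shape != (topology.n_sites,):
            raise ValueError("bfactors must have one value per site")
    with path.open("w") as fh:
        for site, (x, y, z), bf in zip(topology, frame.coords, b):
            name = site.name[:4]
            # PDB convention: names shorter than 4 chars start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            chain = (site.domain or "A")[0]
            resseq = (site.site_id + 1) % 10000
            fh.write(
                f"ATOM  {site.site_id + 1:>5d} {padded:<4s} SIT {chain}"
                f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{bf:6.2f}           C\n"
            )
        fh.write("END\n")
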