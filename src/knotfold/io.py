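"""PDB input/output for C-alpha traces, and schedule configuration files."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
import yaml

from .frenet import CAlphaChain
from .mc import Schedule

__all__ = [
    "MissingResidueWarning",
    "read_calpha_pdb",
    "write_calpha_pdb",
    "read_schedule",
    "write_schedule",
]


class MissingResidueWarning(UserWarning):
    """Gaps in the residue numbering of the selected chain."""


def read_calpha_pdb(path, chain_id: str | None = None,
                    model_index: int = 0) -> CAlphaChain:
    """Extract the C-alpha trace of one chain from a PDB (or mmCIF) file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: the first listed).  Residues are taken in file order; gaps in the
    author residue numbering are reported with a
    :class:`MissingResidueWarning`.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[model_index]
    if chain_id is None:
        if len(model) == 0:
            raise ValueError(f"{path}: no chains")
        chain = model[0]
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            raise ValueError(f"{path}: no chain {chain_id!r}")
    coords = []
    numbers = []
    for res in chain:
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            continue
        best = max(cas, key=lambda a: a.occ)  # max() keeps the first on ties
        coords.append([best.pos.x, best.pos.y, best.pos.z])
        numbers.append(res.seqid.num)
    if not coords:
        raise ValueError(f"{path}: no C-alpha atoms in chain {chain.name!r}")
    gaps = [(numbers[k], numbers[k + 1]) for k in range(len(numbers) - 1)
            if numbers[k + 1] - numbers[k] > 1]
    if gaps:
        warnings.warn(
            f"{path}: residue-numbering gaps {gaps} in chain {chain.name!r}",
            MissingResidueWarning, stacklevel=2)
    return CAlphaChain(np.asarray(coords))


def calpha_pdb_text(chain: CAlphaChain, chain_id: str = "A") -> str:
    """PDB text for a C-alpha-only trace (one ALA residue per position)."""
    lines = []
    for i, (x, y, z) in enumerate(chain.positions, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  ALA {chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_calpha_pdb(chain: CAlphaChain, path, chain_id: str = "A") -> None:
    with open(path, "w") as fh:
        fh.write(calpha_pdb_text(chain, chain_id))


_SCHEDULE_FIELDS = ("beta_start", "n_heating", "n_thermalization", "n_cooling",
                    "heating_multiplier", "cooling_multiplier", "record_stride",
                    "theta_move_probability", "hb_ratio", "n_theta_bins")


def write_schedule(schedule: Schedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({f: getattr(schedule, f) for f in _SCHEDULE_FIELDS}, fh)


def read_schedule(path) -> Schedule:
    """Load a YAML schedule config.

    Either the explicit multipliers or a ``beta_hot`` key (from which the
    multipliers are derived geometrically) must be present.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "beta_hot" in cfg:
        beta_hot = cfg.pop("beta_hot")
        return Schedule.from_beta_range(
            cfg.pop("beta_start"), beta_hot,
            cfg.pop("n_heating"), cfg.pop("n_thermalization"), cfg.pop("n_cooling"),
            **cfg)
    return Schedule(**cfg)
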