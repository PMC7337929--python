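"""File formats: coarse-bead PDB, TSV tables, motif reports.

Coarse-grained models are written as standard PDB ATOM records through
gemmi: one residue per nucleotide carrying its P and C4' beads, chains A/B
(/C/D...) for successive strands, 1-based residue numbering.  Coordinates
survive a write/read round trip to the PDB fixed-width precision (3
decimals).
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import HelixModel
from .motifs import ReducedTopology
from .sampler import ViabilityCounts

__all__ = [
    "write_helix_pdb",
    "write_beads_pdb",
    "read_beads_pdb",
    "write_viability_map",
    "write_summary_tsv",
    "motif_report",
    "write_motif_report",
]

_CHAIN_IDS = "ABCDEFGHIJKLMNOP"


def _bead_chains(helix: HelixModel) -> list[np.ndarray]:
    return [helix.strand5.reshape(-1, 2, 3), helix.strand3.reshape(-1, 2, 3)]


def write_helix_pdb(helices, path) -> None:
    """Write one or more helices as a coarse-bead PDB (chains A/B per
    strand, atoms P and C4', residue name N)."""
    if isinstance(helices, HelixModel):
        helices = [helices]
    chains = []
    for h in helices:
        chains.extend(_bead_chains(h))
    write_beads_pdb(chains, path)


def write_beads_pdb(chains, path) -> None:
    """Write per-chain arrays of shape (n_nt, 2, 3) ((P, C4') per
    nucleotide) or (n_beads, 3) (alternating P/C4' beads) as PDB."""
    st = gemmi.Structure()
    st.name = "pktopo"
    model = gemmi.Model("1")
    for ci, arr in enumerate(chains):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            if len(arr) % 2:
                raise ValueError("flat bead chain must alternate P/C4'")
            arr = arr.reshape(-1, 2, 3)
        chain = gemmi.Chain(_CHAIN_IDS[ci])
        for ri, (p, c4) in enumerate(arr, start=1):
            res = gemmi.Residue()
            res.name = "N"
            res.seqid = gemmi.SeqId(ri, " ")
            for name, pos in (("P", p), ("C4'", c4)):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("P" if name == "P" else "C")
                atom.pos = gemmi.Position(*pos)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    Path(path).write_text(st.make_pdb_string())


def read_beads_pdb(path) -> dict[str, np.ndarray]:
    """Read a coarse-bead PDB back into per-chain (n_nt, 2, 3) arrays."""
    st = gemmi.read_structure(str(path))
    out = {}
    for chain in st[0]:
        rows = []
        for res in chain:
            beads = {a.name: [a.pos.x, a.pos.y, a.pos.z] for a in res}
            rows.append([beads["P"], beads["C4'"]])
        out[chain.name] = np.array(rows)
    return out


def write_viability_map(counts: ViabilityCounts, path) -> None:
    """Per-configuration viability flags as TSV (one row per enumerated or
    sampled configuration; requires counts produced with record=True)."""
    if counts.records is None:
        raise ValueError("counts carry no per-configuration records; rerun "
                         "with record=True")
    pd.DataFrame(counts.records).to_csv(path, sep="\t", index=False)


def write_summary_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def motif_report(topology: ReducedTopology) -> dict:
    """JSON-ready report naming each motif with its size string."""
    motifs = []
    for m in topology.motifs:
        motifs.append({
            "name": m.name,
            "type": m.motif_type,
            "size": m.size_string,
            "helix_sizes": list(m.helix_sizes),
            "loop_sizes": list(m.loop_sizes),
            "residues": {k: list(v) for k, v in m.residue_map.items()},
            **({"l6_closed": m.l6_closed} if m.motif_type == "KISS" else {}),
        })
    return {
        "length": topology.length,
        "motifs": motifs,
        "substitutions": [dict(s, span=list(s["span"]))
                          for s in topology.substitutions],
    }


def write_motif_report(topology: ReducedTopology, path) -> None:
    Path(path).write_text(json.dumps(motif_report(topology), indent=2)
                          + "\n")
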