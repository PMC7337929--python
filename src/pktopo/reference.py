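"""Reference topological-constraint fractions for crystallographic motifs.

Published full-scale enumeration results for 20 pseudoknot motifs and 7
hairpin-hairpin kissing motifs drawn from crystal/NMR structures (named by
PDB id), used as inputs to the summary and grouping operations and as
regression anchors for the fraction arithmetic.  Fractions are stored as
printed, at two significant figures.

Full-scale enumeration constants: R = 1800 rotations (100 axes x 18
angles); translation-grid totals T for the L2 = 0..3 nt minimal bounding
boxes; and the allowed-configuration counts for the 2tpk pseudoknot
(5-1-0-7-7), whose fraction arithmetic N_2 / (R * T) = 4.3E-3 and
N_123 / (R * T) = 7.1E-8 anchors the reporting pipeline.
"""

from __future__ import annotations

from .motifs import MotifSpec, parse_size_string

__all__ = [
    "PK_CASES",
    "KISS_CASES",
    "ROTATIONS_FULL",
    "GRID_TOTALS_FULL",
    "TPK_COUNTS",
    "pk_reference_cases",
    "kiss_reference_cases",
]

#: R at the full-scale profile: 100 quasi-uniform axes x 18 angles.
ROTATIONS_FULL = 1800

#: Published translation-grid totals T for HLH linker length L2 = 0..3 nt.
GRID_TOTALS_FULL = {0: 23548, 1: 8820, 2: 4913, 3: 3840}

#: Allowed-configuration counts for the 2tpk pseudoknot (5-1-0-7-7) at the
#: full-scale profile (N_tot = 1800 * 23548).
TPK_COUNTS = {"2": 181_249, "12": 3, "23": 63_791, "123": 3}

#: (pdb_id, size H1-L1-L2-L3-H2, F_2, F_12, F_23, F_PK)
PK_CASES = [
    ("1a60", "3-4-0-3-5", 5.2e-3, 1.8e-4, 2.0e-4, 4.6e-5),
    ("1e95", "6-1-0-9-6", 3.2e-3, 1.8e-6, 2.9e-3, 1.8e-6),
    ("1hvu", "5-2-0-3-6", 4.3e-3, 6.5e-6, 3.8e-5, 1.2e-7),
    ("1ymo", "6-8-0-8-9", 3.2e-3, 2.5e-3, 2.2e-3, 1.7e-3),
    ("2n6q", "4-3-0-4-8", 4.9e-3, 3.9e-5, 2.8e-4, 9.2e-6),
    ("2tpk", "5-1-0-7-7", 4.3e-3, 7.1e-8, 1.5e-3, 7.1e-8),
    ("4p5j", "3-3-0-3-6", 5.2e-3, 4.2e-5, 2.0e-4, 2.1e-5),
    ("2m8k", "5-6-0-5-12", 4.3e-3, 5.8e-4, 2.4e-4, 2.6e-5),
    ("2ap0", "5-1-1-9-3", 2.8e-2, 1.0e-4, 2.6e-2, 1.0e-4),
    ("1kpd", "5-3-1-7-5", 2.7e-2, 3.8e-4, 9.6e-3, 3.1e-4),
    ("1rnk", "5-2-1-8-6", 2.7e-2, 6.3e-5, 1.7e-2, 6.3e-5),
    ("1yg4", "5-2-1-9-3", 2.8e-2, 4.6e-4, 2.6e-2, 4.5e-4),
    ("2a43", "4-2-1-9-3", 3.1e-2, 4.6e-4, 3.0e-2, 4.6e-4),
    ("2rp1", "5-2-1-8-3", 2.8e-2, 4.6e-4, 2.0e-2, 3.8e-4),
    ("2xdd", "4-4-1-6-3", 3.1e-2, 3.6e-3, 1.0e-2, 1.6e-3),
    ("4ato", "3-3-1-5-4", 3.2e-2, 8.6e-4, 6.9e-3, 5.4e-4),
    ("437d", "5-2-1-7-3", 2.8e-2, 4.6e-4, 1.2e-2, 2.3e-4),
    ("4rmo", "5-3-2-9-5", 5.6e-2, 8.3e-4, 4.2e-2, 8.3e-4),
    ("1kaj", "5-3-2-8-4", 5.7e-2, 1.6e-3, 3.1e-2, 1.4e-3),
    ("2m58", "3-3-3-7-4", 9.7e-2, 3.3e-3, 6.1e-2, 3.0e-3),
]

#: (pdb_id, size (H1-H2-H3)-(L1-..-L6), F_24, F_124, F_234, F_245, F_246,
#:  F_KISS)
KISS_CASES = [
    ("1e8o", "(7-2-4)-(3-1-4-1-5-2)",
     8.5e-4, 6.0e-5, 3.9e-5, 3.6e-5, 2.7e-5, 1.4e-7),
    ("3skl", "(6-2-7)-(5-0-8-0-2-7)",
     2.3e-5, 9.4e-6, 6.7e-6, 4.8e-7, 1.2e-5, 4.4e-8),
    ("3ds7", "(7-2-6)-(5-0-8-0-5-7)",
     2.0e-5, 8.8e-6, 6.8e-6, 9.4e-6, 1.5e-5, 1.0e-6),
    ("3ivn", "(6-2-5)-(6-1-8-1-6-7)",
     9.4e-4, 6.5e-4, 2.8e-4, 7.2e-4, 7.1e-4, 1.3e-4),
    ("4lx5", "(6-2-6)-(6-1-8-0-5-7)",
     1.5e-4, 9.9e-5, 4.2e-5, 7.5e-5, 9.8e-5, 1.1e-5),
    ("4wfl", "(4-5-5)-(4-2-3-3-3-2)",
     5.2e-3, 1.7e-4, 4.0e-5, 9.4e-5, 3.7e-5, 9.9e-11),
    ("4uyk", "(5-5-4)-(3-1-4-4-5-2)",
     3.4e-3, 4.1e-5, 8.2e-5, 3.3e-4, 4.1e-5, 2.5e-9),
]

_PK_LABELS = ("2", "12", "23", "123")
_KISS_LABELS = ("24", "124", "234", "245", "246", "123456")


def pk_reference_cases() -> list[tuple[str, MotifSpec, dict]]:
    """Reference PK cases as (name, MotifSpec, {subset: fraction}) triples,
    ready for :func:`pktopo.analysis.summarize_cases`."""
    out = []
    for pdb, size, *fs in PK_CASES:
        out.append((pdb, parse_size_string(size),
                    dict(zip(_PK_LABELS, fs))))
    return out


def kiss_reference_cases() -> list[tuple[str, MotifSpec, dict]]:
    """Reference KISS cases as (name, MotifSpec, {subset: fraction})."""
    out = []
    for pdb, size, *fs in KISS_CASES:
        out.append((pdb, parse_size_string(size),
                    dict(zip(_KISS_LABELS, fs))))
    return out
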