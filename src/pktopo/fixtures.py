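"""Deterministic toy fixtures: dot-bracket strings, a toy template
database, and reference helix PDBs.

No external download is needed anywhere in the package: these generators
produce dot-bracket strings realizing the reference motif size wirings, a
small template database (including the kissing-motif worked-example
template of size (5-5-4)-(3-1-4-4-5-2)), and idealized helix coordinate
files.  Output is byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import math
from pathlib import Path

from .config import RunConfig, REDUCED_PROFILE
from .geometry import make_transform
from .motifs import MotifSpec, parse_size_string
from .reference import KISS_CASES, PK_CASES
from .templates import TemplateRecord, save_template_db
from . import io as pio

__all__ = [
    "pk_dotbracket",
    "kiss_dotbracket",
    "toy_template_db",
    "generate_fixtures",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("pk-strings", "kiss-strings", "toy-template-db",
                 "helix-pdb")


def pk_dotbracket(h1: int, l1: int, l2: int, l3: int, h2: int) -> str:
    """Dot-bracket string realizing the H-type pseudoknot wiring
    H1a-L1-H2a-L2-H1b-L3-H2b for the given sizes."""
    return ("(" * h1 + "." * l1 + "[" * h2 + "." * l2 + ")" * h1
            + "." * l3 + "]" * h2)


def kiss_dotbracket(spec: MotifSpec, enclose: int = 3) -> str:
    """Dot-bracket string realizing a kissing-motif size wiring.

    The six-loop sizes require L6 >= 2; the L6 circuit is realized by
    wrapping the two kissing hairpins in an ``enclose``-bp helix with the
    L6 - 2 free nucleotides split between the two flanks (La gets the
    smaller half), so that reduction of the enclosing helix to its terminal
    base pair recovers L6 = La + Lb + 2.
    """
    h1, h2, h3 = spec.helix_sizes
    l1, l2, l3, l4, l5, l6 = spec.loop_sizes
    if l6 < 2:
        raise ValueError("an enclosed KISS needs an effective L6 >= 2")
    la = (l6 - 2) // 2
    lb = l6 - 2 - la
    core = ("(" * h1 + "." * l1 + "[" * h2 + "." * l2 + ")" * h1
            + "." * l3 + "(" * h3 + "." * l4 + "]" * h2 + "." * l5
            + ")" * h3)
    return ("(" * enclose + "." * la + core + "." * lb + ")" * enclose)


def toy_template_db(config: RunConfig = REDUCED_PROFILE
                    ) -> list[TemplateRecord]:
    """Small deterministic template DB with plausible (not fitted)
    inter-helix transforms.

    Contains the worked-example kissing template of size
    (5-5-4)-(3-1-4-4-5-2), a second KISS record, and two PK records with
    near-coaxial stacking transforms.
    """
    rise = config.rise

    def stack(n_below: int, alpha_frac: float = 0.5):
        # flip about x (axis theta=pi/2, phi=0, angle pi) so the mobile
        # helix body extends up, then lift it above the reference helix
        return make_transform(math.pi / 2, 0.0, math.pi,
                              (0.0, 0.0, n_below * rise))

    db = []
    for tid, size in [("1yg4", "5-2-1-9-3"), ("2tpk", "5-1-0-7-7")]:
        spec = parse_size_string(size)
        db.append(TemplateRecord(tid, "PK", list(spec.helix_sizes),
                                 list(spec.loop_sizes), [stack(1)]))
    for tid, size in [("4uyk", "(5-5-4)-(3-1-4-4-5-2)"),
                      ("4wfl", "(4-5-5)-(4-2-3-3-3-2)")]:
        spec = parse_size_string(size)
        h2 = spec.helix_sizes[1]
        t2 = stack(1)
        t3 = make_transform(0.0, 0.0, 0.0, (0.0, 0.0, (h2 + 1) * rise))
        db.append(TemplateRecord(tid, "KISS", list(spec.helix_sizes),
                                 list(spec.loop_sizes), [t2, t3]))
    return db


def generate_fixtures(kind: str, seed: int = 0, out_dir=".",
                      config: RunConfig = REDUCED_PROFILE) -> list[Path]:
    """Write deterministic fixture files of the given kind; returns the
    paths written.  ``seed`` is recorded for provenance (all fixtures are
    fully deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "pk-strings":
        lines = [f"# pk dot-bracket fixtures (seed={seed})"]
        for pdb, size, *_ in PK_CASES:
            spec = parse_size_string(size)
            h1, h2 = spec.helix_sizes
            l1, l2, l3 = spec.loop_sizes
            lines.append(f"{pdb}\t{size}\t{pk_dotbracket(h1, l1, l2, l3, h2)}")
        p = out / "pk_strings.tsv"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    elif kind == "kiss-strings":
        lines = [f"# kiss dot-bracket fixtures (seed={seed})"]
        for pdb, size, *_ in KISS_CASES:
            spec = parse_size_string(size)
            lines.append(f"{pdb}\t{size}\t{kiss_dotbracket(spec)}")
        p = out / "kiss_strings.tsv"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    elif kind == "toy-template-db":
        p = out / "toy_templates.yaml"
        save_template_db(toy_template_db(config), p)
        written.append(p)
    elif kind == "helix-pdb":
        from .geometry import build_a_form_helix
        for n_bp in (3, 5, 11):
            p = out / f"helix_a_form_{n_bp}bp.pdb"
            pio.write_helix_pdb(build_a_form_helix(n_bp, config), p)
            written.append(p)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from "
                         f"{FIXTURE_KINDS}")
    return written
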