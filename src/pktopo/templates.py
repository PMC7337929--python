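"""Motif-topology templates: storage, size-difference scoring, placement.

A template records the inter-helix rigid-body transforms of a known PK or
KISS motif together with its helix and loop sizes.  Queries are matched by
motif type and scored with the size-difference scheme

    S = a * sum |dH|  +  sum b_loop * |dL|

with helix weight a = 2 and loop weight b = 5 for the short, strongly
constraining loops (L2 of a PK; L2 and L4 of a KISS) and b = 1 for all
others; elements are compared positionally (H1 with H1, L1 with L1, ...).
The best template's transforms are then used to place A-form helices of the
query's sizes, giving a coarse-grained global scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .config import RunConfig, REDUCED_PROFILE
from .geometry import RigidTransform, extract_params, make_transform
from .motifs import MotifSpec, parse_size_string
from .sampler import _Scene, loop_reach

__all__ = [
    "TemplateRecord",
    "ScoreParams",
    "Scaffold",
    "TemplateNotFoundError",
    "score_template",
    "rank_templates",
    "place_helices",
    "load_template_db",
    "save_template_db",
]

#: 0-based indices of the strongly constraining loops, per motif type
STRONG_LOOPS = {"PK": (1,), "KISS": (1, 3)}


class TemplateNotFoundError(LookupError):
    """No template of the query's motif type exists in the database."""


@dataclass(frozen=True)
class ScoreParams:
    """Weights of the size-difference scoring scheme."""

    a: int = 2          # helix size-difference weight
    b_strong: int = 5   # weight for L2 (PK) and L2, L4 (KISS)
    b_weak: int = 1     # weight for all other loops

    def __post_init__(self):
        if min(self.a, self.b_strong, self.b_weak) <= 0:
            raise ValueError("all score weights must be > 0")


@dataclass
class TemplateRecord:
    """A stored motif topology scorable against a query motif."""

    template_id: str
    motif_type: str
    helix_sizes: list
    loop_sizes: list
    transforms: list    # RigidTransform of helix i+2 relative to helix 1

    def __post_init__(self):
        arity = {"PK": (2, 3), "KISS": (3, 6)}.get(self.motif_type)
        if arity is None:
            raise ValueError(f"unsupported motif type {self.motif_type!r}")
        nh, nl = arity
        if len(self.helix_sizes) != nh or len(self.loop_sizes) != nl:
            raise ValueError(
                f"{self.motif_type} template needs {nh} helices and "
                f"{nl} loops")
        if len(self.transforms) != nh - 1:
            raise ValueError("transform count must be helix count - 1")

    @property
    def spec(self) -> MotifSpec:
        return MotifSpec(self.motif_type, list(self.helix_sizes),
                         list(self.loop_sizes))

    @property
    def size_string(self) -> str:
        return self.spec.size_string


def score_template(query: MotifSpec, template: TemplateRecord,
                   params: ScoreParams = ScoreParams()) -> int:
    """Size-difference score between a query motif and a template.

    Symmetric, non-negative, zero iff all sizes match; raises ``ValueError``
    on motif-type or arity mismatch.
    """
    if query.motif_type != template.motif_type:
        raise ValueError(
            f"motif type mismatch: query {query.motif_type}, template "
            f"{template.motif_type}")
    if (len(query.helix_sizes) != len(template.helix_sizes)
            or len(query.loop_sizes) != len(template.loop_sizes)):
        raise ValueError("element counts do not match")
    strong = STRONG_LOOPS[query.motif_type]
    s = params.a * sum(abs(q - t) for q, t in
                       zip(query.helix_sizes, template.helix_sizes))
    for i, (q, t) in enumerate(zip(query.loop_sizes, template.loop_sizes)):
        b = params.b_strong if i in strong else params.b_weak
        s += b * abs(q - t)
    return s


def _strong_delta(query: MotifSpec, template: TemplateRecord) -> int:
    strong = STRONG_LOOPS[query.motif_type]
    return sum(abs(query.loop_sizes[i] - template.loop_sizes[i])
               for i in strong)


def rank_templates(query: MotifSpec, db: Sequence[TemplateRecord],
                   params: ScoreParams = ScoreParams()
                   ) -> list[tuple[int, TemplateRecord]]:
    """Templates of the query's motif type, ascending by score.

    Ties break on the smaller strong-loop size difference, then on the
    lexicographic template id, so the ranking is deterministic under any
    database permutation.
    """
    cands = [t for t in db if t.motif_type == query.motif_type]
    if not cands:
        raise TemplateNotFoundError(
            f"no {query.motif_type} template in database")
    scored = [(score_template(query, t, params), t) for t in cands]
    scored.sort(key=lambda st: (st[0], _strong_delta(query, st[1]),
                                st[1].template_id))
    return scored


# ---------------------------------------------------------------------------
# scaffold placement
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    """A-form helices of the query's sizes placed on template transforms."""

    spec: MotifSpec
    template_id: str
    helices: list               # placed HelixModel objects
    transforms: list            # the template transforms used (rel. helix 1)
    loop_gaps: dict             # loop label -> anchor-anchor distance, A
    config: RunConfig

    def loops_in_reach(self) -> dict:
        """Per-loop flag: anchor gap within the loop's reach bound."""
        sizes = dict(zip("123456", self.spec.loop_sizes))
        out = {}
        for lab, gap in self.loop_gaps.items():
            out[lab] = gap <= loop_reach(sizes[lab], self.config)
        return out


def place_helices(query: MotifSpec, template: TemplateRecord,
                  config: RunConfig = REDUCED_PROFILE) -> Scaffold:
    """Build A-form helices of the query's sizes and position them with the
    template's inter-helix transforms (helix 1 fixed at the reference
    frame).  Helix internal geometry is untouched; only the helix body
    lengths differ from the template when sizes differ.
    """
    if query.motif_type != template.motif_type:
        raise ValueError("query and template motif types differ")
    scene = _Scene(query, config)
    placements = [(np.eye(3), np.zeros(3))]
    for t in template.transforms:
        placements.append((t.rotation, t.translation))
    placed = scene.place(placements)
    helices = [h.transformed(_as_transform(R, t))
               for h, (R, t) in zip(scene.helices, placements)]
    labels = ["1", "2", "3"] if query.motif_type == "PK" else list("123456")
    gaps = {}
    for lab in labels:
        if query.motif_type == "KISS" and lab == "6" and not query.l6_closed:
            continue
        gaps[lab] = placed.loop_gap(lab)
    return Scaffold(spec=query, template_id=template.template_id,
                    helices=helices, transforms=list(template.transforms),
                    loop_gaps=gaps, config=config)


def _as_transform(R: np.ndarray, t: np.ndarray) -> RigidTransform:
    from .geometry import transform_from_matrix
    return transform_from_matrix(R, t)


def template_from_scaffold(template_id: str, spec: MotifSpec,
                           frames: Sequence) -> TemplateRecord:
    """Template whose transforms are extracted from placed interface
    frames (frame of helix 1 first)."""
    transforms = [extract_params(frames[0], f) for f in frames[1:]]
    return TemplateRecord(template_id, spec.motif_type,
                          list(spec.helix_sizes), list(spec.loop_sizes),
                          transforms)


# ---------------------------------------------------------------------------
# template database (structured text)
# ---------------------------------------------------------------------------

def save_template_db(db: Sequence[TemplateRecord], path) -> None:
    """Write templates to a YAML database (sizes in the standard motif
    notation, transforms as six-number [theta, phi, alpha, dx, dy, dz])."""
    recs = []
    for t in db:
        recs.append({
            "template_id": t.template_id,
            "motif_type": t.motif_type,
            "size": t.size_string,
            "transforms": [[float(v) for v in tr.params]
                           for tr in t.transforms],
        })
    Path(path).write_text(yaml.safe_dump({"version": 1, "templates": recs},
                                         sort_keys=False))


def load_template_db(path) -> list[TemplateRecord]:
    data = yaml.safe_load(Path(path).read_text())
    out = []
    for rec in data.get("templates", []):
        spec = parse_size_string(rec["size"])
        transforms = [make_transform(p[0], p[1], p[2], p[3:6])
                      for p in rec["transforms"]]
        out.append(TemplateRecord(rec["template_id"], rec["motif_type"],
                                  list(spec.helix_sizes),
                                  list(spec.loop_sizes), transforms))
    return out
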