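"""Water-pathway transit counting and the glutamate water-gate analysis.

The pump has three water pathways connecting the binding pocket to bulk
solvent: an extracellular pathway near site I and two intracellular ones,
the N-terminal pathway near site II and the C-terminal pathway near
site III.  Each pathway is modelled as a corridor: a cylinder of radius
``corridor_radius`` between a *mouth* point (bulk end) and a *site* point
(pocket end), with a spherical zone of the same radius about each end.

A water molecule scores one **inward** transit when its oxygen passes
from the mouth zone to the site zone while staying inside the corridor
in between; outward transits are the mirror image, and re-entries count
separately.  Leaving the corridor voids the attempt.

The water-gate hypothesis — each site's glutamate, when protonated,
closes the associated pathway — is tested by contrasting flux between a
reference state with all three glutamates protonated (e.g. ``3[EEE]``)
and states that move one proton from a Glu to the same-site Asp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .states import BindingSiteRegistry, ProtonationState
from .trajectory import Trajectory

__all__ = [
    "PathwayDefinition",
    "TransitRecord",
    "FluxSummary",
    "ContrastDesignError",
    "PATHWAY_SITE_MAP",
    "count_transits",
    "flux_summary",
    "gate_association_test",
]

#: Canonical pathway -> binding-site association.
PATHWAY_SITE_MAP = {"extracellular": "I", "N-terminal": "II", "C-terminal": "III"}


class ContrastDesignError(ValueError):
    """States do not form the designed Glu<->Asp proton-swap contrast."""


@dataclass(frozen=True)
class PathwayDefinition:
    """Geometric corridor of one water pathway (coordinates in Å)."""

    name: str
    mouth_point: tuple[float, float, float]
    site_point: tuple[float, float, float]
    corridor_radius: float = 5.0
    associated_site: str = ""

    def __post_init__(self) -> None:
        if self.corridor_radius <= 0:
            raise ValueError("corridor_radius must be positive")
        if np.allclose(self.mouth_point, self.site_point):
            raise ValueError("mouth and site points must differ")
        if not self.associated_site:
            object.__setattr__(self, "associated_site",
                               PATHWAY_SITE_MAP.get(self.name, ""))


@dataclass(frozen=True)
class TransitRecord:
    water_id: str
    pathway: str
    entry_frame: int
    completion_frame: int
    direction: str  # inward | outward

    def __post_init__(self) -> None:
        if not self.entry_frame < self.completion_frame:
            raise ValueError("entry frame must precede completion frame")


@dataclass
class FluxSummary:
    """Inward-transit statistics for one (state, pathway) across replicas."""

    pathway: str
    counts: np.ndarray  # per replica
    mean: float
    se: Optional[float]  # None with a single replica
    gate_call: str  # open | closed


def _zone_labels(pos: np.ndarray, pathway: PathwayDefinition) -> np.ndarray:
    """Per-frame zone of one water: M(outh), S(ite), C(orridor), O(utside).

    Zone spheres take priority over the corridor body; if the two spheres
    overlap, the nearer endpoint wins.
    """
    mouth = np.asarray(pathway.mouth_point, dtype=float)
    site = np.asarray(pathway.site_point, dtype=float)
    r2 = pathway.corridor_radius ** 2
    d2_m = ((pos - mouth) ** 2).sum(axis=1)
    d2_s = ((pos - site) ** 2).sum(axis=1)
    axis = site - mouth
    length2 = float(axis @ axis)
    t = ((pos - mouth) @ axis) / length2  # axial fraction
    foot = mouth + t[:, None] * axis
    radial2 = ((pos - foot) ** 2).sum(axis=1)
    in_cyl = (t >= 0.0) & (t <= 1.0) & (radial2 <= r2)

    labels = np.full(pos.shape[0], "O", dtype="<U1")
    labels[in_cyl] = "C"
    in_m = d2_m <= r2
    in_s = d2_s <= r2
    both = in_m & in_s
    labels[in_m & ~both] = "M"
    labels[in_s & ~both] = "S"
    labels[both] = np.where(d2_m[both] <= d2_s[both], "M", "S")
    return labels


def count_transits(traj: Trajectory, pathway: PathwayDefinition
                   ) -> list[TransitRecord]:
    """Enumerate completed transits of every water through one pathway.

    The zone-sequence rule: a transit is recorded when a water reaches
    one end zone having last visited the other end zone, with every
    intervening frame inside the corridor (zones included).  Any frame
    outside the corridor resets the attempt.
    """
    records: list[TransitRecord] = []
    waters = traj.water_coords()  # (F, W, 3)
    ids = [traj.particles[i].id for i in traj.water_indices]
    for w in range(waters.shape[1]):
        labels = _zone_labels(waters[:, w, :], pathway)
        last_zone: Optional[str] = None
        last_zone_frame = -1
        for f, z in enumerate(labels):
            if z == "O":
                last_zone = None
            elif z == "M":
                if last_zone == "S":
                    records.append(TransitRecord(ids[w], pathway.name,
                                                 last_zone_frame, f, "outward"))
                last_zone, last_zone_frame = "M", f
            elif z == "S":
                if last_zone == "M":
                    records.append(TransitRecord(ids[w], pathway.name,
                                                 last_zone_frame, f, "inward"))
                last_zone, last_zone_frame = "S", f
            # z == "C": attempt continues
    records.sort(key=lambda r: (r.completion_frame, r.water_id))
    return records


def flux_summary(per_replica_transits: Sequence[Sequence[TransitRecord] | int],
                 pathway: str = "", open_baseline: float = 1.0) -> FluxSummary:
    """Mean ± standard error of inward transit counts across replicas.

    The gate is called *open* when the mean inward flux exceeds
    ``open_baseline`` transits per replica per window.  With a single
    replica the standard error is reported absent (None).
    """
    if len(per_replica_transits) == 0:
        raise ValueError("flux_summary needs at least one replica")
    counts = []
    for rep in per_replica_transits:
        if isinstance(rep, (int, np.integer)):
            counts.append(int(rep))
        else:
            counts.append(sum(1 for r in rep if r.direction == "inward"))
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("transit counts must be non-negative")
    mean = float(counts.mean())
    se = (float(counts.std(ddof=1) / np.sqrt(len(counts)))
          if len(counts) >= 2 else None)
    gate = "open" if mean > open_baseline else "closed"
    return FluxSummary(pathway=pathway, counts=counts, mean=mean, se=se,
                       gate_call=gate)


def _glu_protonated(state: ProtonationState, registry: BindingSiteRegistry,
                    site_label: str) -> bool:
    glu, _ = registry.site_residues(site_label)
    return state.flags[glu]


def gate_association_test(flux: Mapping[tuple[str, str], FluxSummary],
                          states: Sequence[ProtonationState],
                          registry: BindingSiteRegistry,
                          open_baseline: float = 1.0) -> pd.DataFrame:
    """Associate per-site Glu protonation with pathway flux.

    Expects a reference state whose three glutamates are all protonated
    plus, for each site, a contrast state identical except that the
    site's proton moved Glu -> Asp (code E -> D).  Returns one row per
    pathway with the mean flux under the protonated and deprotonated
    glutamate, the direction of change, and an exception flag for any
    extra state whose deprotonated-Glu pathway nonetheless stays closed
    (the occlusion signature of 4-proton states).
    """
    by_symbol = {s.symbol: s for s in states}
    site_order = registry.site_labels
    reference = None
    for s in states:
        if all(_glu_protonated(s, registry, lab) for lab in site_order):
            reference = s
            break
    if reference is None:
        raise ContrastDesignError(
            "no reference state with all three glutamates protonated")

    contrasts: dict[str, ProtonationState] = {}
    extras: list[ProtonationState] = []
    for s in states:
        if s.symbol == reference.symbol:
            continue
        diff_sites = [i for i, (a, b) in enumerate(zip(s.codes, reference.codes))
                      if a != b]
        if (len(diff_sites) == 1 and reference.codes[diff_sites[0]] == "E"
                and s.codes[diff_sites[0]] == "D"):
            contrasts[site_order[diff_sites[0]]] = s
        else:
            extras.append(s)

    if not contrasts:
        raise ContrastDesignError(
            "no contrast state differing from the reference by one E->D swap")

    site_to_pathway = {v: k for k, v in PATHWAY_SITE_MAP.items()}
    rows = []
    for lab in site_order:
        pathway = site_to_pathway[lab]
        glu, _ = registry.site_residues(lab)
        ref_flux = flux[(reference.symbol, pathway)]
        row = {"pathway": pathway, "site": lab, "glu": str(glu),
               "flux_glu_protonated": ref_flux.mean,
               "flux_glu_deprotonated": np.nan, "direction": "no contrast",
               "note": ""}
        if lab in contrasts:
            contrast = contrasts[lab]
            con_flux = flux[(contrast.symbol, pathway)]
            row["flux_glu_deprotonated"] = con_flux.mean
            if con_flux.mean > ref_flux.mean and con_flux.gate_call == "open":
                row["direction"] = "opens on deprotonation"
                row["note"] = (f"{glu} deprotonation opens the {pathway} "
                               f"pathway ({reference.symbol} -> {contrast.symbol})")
            elif con_flux.mean == ref_flux.mean:
                row["direction"] = "no association"
            else:
                row["direction"] = "no opening"
        rows.append(row)

    # extra states carrying MORE protons than the reference yet keeping a
    # deprotonated-Glu pathway closed: the occlusion exception
    for s in extras:
        if s.n_protons <= reference.n_protons:
            continue
        for lab in site_order:
            pathway = site_to_pathway[lab]
            key = (s.symbol, pathway)
            if key not in flux or _glu_protonated(s, registry, lab):
                continue
            fs = flux[key]
            if fs.gate_call == "closed":
                glu, _ = registry.site_residues(lab)
                rows.append({"pathway": pathway, "site": lab, "glu": str(glu),
                             "flux_glu_protonated": np.nan,
                             "flux_glu_deprotonated": fs.mean,
                             "direction": "exception",
                             "note": (f"{s.symbol}: {glu} deprotonated but the "
                                      f"{pathway} pathway stays closed")})
    return pd.DataFrame(rows)
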