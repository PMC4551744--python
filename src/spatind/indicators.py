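"""Area-weighted spatial indicators for survey density fields.

All indicators operate on one species slice of a survey: positions
``(x, y)`` in nmi, densities ``z`` (t/nmi^2) and areas of influence ``s``
(nmi^2).  Each sample's contribution to any abundance integral is
``z * s`` (tonnes), so irregular survey sectors are handled by the weights
rather than by resampling.

The suite covers location (centre of gravity), dispersion (inertia and
isotropy), occupation (positive area), aggregation (spreading and
equivalent area, packing density), patchiness (major patches within a
threshold distance) and between-species overlap (global index of
collocation), plus the two classical survey biomass estimators.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .survey import SurveyDataset, inverse_project

__all__ = [
    "IndicatorSet",
    "Patch",
    "PatchSet",
    "UndefinedIndicatorError",
    "centre_of_gravity",
    "inertia_and_isotropy",
    "positive_area",
    "spreading_area",
    "equivalent_area",
    "identify_patches",
    "global_index_of_collocation",
    "estimate_biomass",
    "packing_density",
    "compute_indicator_set",
    "compute_indicator_table",
]


class UndefinedIndicatorError(ValueError):
    """An indicator is undefined for this input (e.g. zero total abundance)."""


def _as_arrays(x, y, z, s):
    x, y, z, s = (np.asarray(a, dtype=float) for a in (x, y, z, s))
    if not (x.shape == y.shape == z.shape == s.shape):
        raise ValueError("x, y, z, s must have equal shapes")
    return x, y, z, s


# ---------------------------------------------------------------------------
# location & dispersion
# ---------------------------------------------------------------------------

def centre_of_gravity(x, y, z, s) -> tuple[float, float]:
    """Abundance-weighted mean location: CG = sum(z s x)/sum(z s)."""
    x, y, z, s = _as_arrays(x, y, z, s)
    w = z * s
    q = w.sum()
    if q <= 0:
        raise UndefinedIndicatorError("centre of gravity undefined: total abundance is zero")
    return float((w * x).sum() / q), float((w * y).sum() / q)


def inertia_and_isotropy(x, y, z, s) -> tuple[float, float, np.ndarray]:
    """Dispersion about the CG and its directional balance.

    Inertia is the abundance-weighted mean squared distance from the CG
    (nmi^2).  The weighted covariance of positions has eigenvalues
    ``l1 >= l2`` summing to the inertia; isotropy = sqrt(l2/l1) is 1 for a
    circular cloud and 0 for a collinear one.  A point population (zero
    inertia) is defined maximally isotropic.  Returns
    (inertia, isotropy, principal axes as rows).
    """
    x, y, z, s = _as_arrays(x, y, z, s)
    cgx, cgy = centre_of_gravity(x, y, z, s)
    w = z * s
    q = w.sum()
    dx, dy = x - cgx, y - cgy
    cov = np.array([
        [(w * dx * dx).sum(), (w * dx * dy).sum()],
        [(w * dx * dy).sum(), (w * dy * dy).sum()],
    ]) / q
    evals, evecs = np.linalg.eigh(cov)
    l2, l1 = float(max(evals[0], 0.0)), float(max(evals[1], 0.0))
    if l2 < 1e-12 * l1:  # collinear up to rounding noise
        l2 = 0.0
    inertia = l1 + l2
    isotropy = 1.0 if l1 <= 0 else float(np.sqrt(l2 / l1))
    return inertia, isotropy, evecs.T[::-1]


# ---------------------------------------------------------------------------
# occupation & aggregation
# ---------------------------------------------------------------------------

def positive_area(z, s) -> float:
    """PA = total area of influence of samples with z > 0 (nmi^2)."""
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    return float(s[z > 0].sum())


def spreading_area(z, s) -> float:
    """SA (nmi^2), from the area-cumulated abundance curve.

    Samples are ranked by decreasing density; with Q(T) the abundance
    accumulated over the T highest-density area, SA = 2 int (Q - Q(T)) dT / Q.
    Equals PA for a uniform field and shrinks as abundance concentrates.
    """
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    q = float((z * s).sum())
    if q <= 0:
        raise UndefinedIndicatorError("spreading area undefined: total abundance is zero")
    order = np.argsort(-z, kind="stable")
    zs, ss = z[order], s[order]
    qi = np.cumsum(zs * ss)
    return float(2.0 * np.sum(ss * (q - qi + zs * ss / 2.0)) / q)


def equivalent_area(z, s) -> float:
    """EA = Q^2 / sum(z^2 s): area occupied at the mean density per individual."""
    z = np.asarray(z, dtype=float)
    s = np.asarray(s, dtype=float)
    q = float((z * s).sum())
    if q <= 0:
        raise UndefinedIndicatorError("equivalent area undefined: total abundance is zero")
    return float(q * q / np.sum(z * z * s))


def packing_density(biomass: float, pa: float) -> float:
    """Pck = total biomass / positive area (t/nmi^2)."""
    if pa <= 0:
        raise UndefinedIndicatorError("packing density undefined: positive area is zero")
    return biomass / pa


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Patch:
    centre: tuple[float, float]     # abundance-weighted centre, nmi
    abundance: float                # t
    members: list[int]              # indices into the input arrays


@dataclasses.dataclass
class PatchSet:
    patches: list[Patch]
    dlim: float
    min_abundance_fraction: float
    total_abundance: float

    def __iter__(self):
        return iter(self.patches)

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_major(self) -> int:
        """Patches holding strictly more than the retention fraction of Q."""
        thr = self.min_abundance_fraction * self.total_abundance
        return sum(1 for p in self.patches if p.abundance > thr)


def identify_patches(x, y, z, s, dlim: float = 20.0,
                     min_fraction: float = 0.10) -> PatchSet:
    """Group positive samples into patches by sequential aggregation.

    Positive samples are processed in decreasing density order (ties keep
    input order).  The densest sample founds patch 1 at its location; each
    subsequent sample joins the nearest patch centre if it lies within
    ``dlim`` nmi (ties go to the lowest patch index), else founds a new
    patch.  Centres are abundance-weighted and updated as members join, so
    membership is evaluated against the centre at assignment time.  Major
    patches are those holding > ``min_fraction`` of total abundance.
    """
    x, y, z, s = _as_arrays(x, y, z, s)
    q = float((z * s).sum())
    pos = np.flatnonzero(z > 0)
    order = pos[np.argsort(-z[pos], kind="stable")]
    patches: list[Patch] = []
    centres = np.empty((0, 2))
    weights = np.empty(0)
    for i in order:
        w = z[i] * s[i]
        p = np.array([x[i], y[i]])
        if len(patches):
            d = np.hypot(centres[:, 0] - p[0], centres[:, 1] - p[1])
            j = int(np.argmin(d))
            if d[j] <= dlim:
                patches[j].members.append(int(i))
                patches[j].abundance += w
                centres[j] = (centres[j] * weights[j] + p * w) / (weights[j] + w)
                weights[j] += w
                patches[j].centre = (float(centres[j, 0]), float(centres[j, 1]))
                continue
        patches.append(Patch((float(p[0]), float(p[1])), w, [int(i)]))
        centres = np.vstack([centres, p])
        weights = np.append(weights, w)
    return PatchSet(patches, dlim, min_fraction, q)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def global_index_of_collocation(pop1, pop2) -> float:
    """GIC between two populations sharing one projection.

    ``pop`` is a tuple ``(x, y, z, s)``.  GIC = 1 - dCG^2/(dCG^2 + I1 + I2)
    with dCG the planar distance between the centres of gravity: 0 when two
    point populations sit apart, 1 when the CGs coincide (including the
    degenerate two-coincident-points case).
    """
    cg1 = centre_of_gravity(*pop1)
    cg2 = centre_of_gravity(*pop2)
    i1, _, _ = inertia_and_isotropy(*pop1)
    i2, _, _ = inertia_and_isotropy(*pop2)
    d2 = (cg1[0] - cg2[0]) ** 2 + (cg1[1] - cg2[1]) ** 2
    denom = d2 + i1 + i2
    if denom == 0.0:
        return 1.0
    return float(1.0 - d2 / denom)


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

def estimate_biomass(dataset: SurveyDataset, species: str, method: str = "edsu") -> float:
    """Survey biomass (t) by EDSU or transect integration.

    ``edsu``: Q = sum(z_i s_i) over all EDSUs.  ``transect``: each transect
    contributes its mean density times its area of influence (the sum of its
    member EDSU areas); with equal EDSU areas within a transect the two
    estimators coincide.
    """
    z = dataset.density(species)
    s = dataset.area_influence
    if method == "edsu":
        return float((z * s).sum())
    if method == "transect":
        if "transect_id" not in dataset.data.columns or dataset.data["transect_id"].isna().any():
            raise ValueError("transect method requires transect_id on every record")
        df = pd.DataFrame({"t": dataset.data["transect_id"].to_numpy(), "z": z, "s": s})
        per = df.groupby("t", sort=False).agg(zbar=("z", "mean"), S=("s", "sum"))
        return float((per["zbar"] * per["S"]).sum())
    raise ValueError(f"unknown method {method!r}; use 'edsu' or 'transect'")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IndicatorSet:
    """The full indicator vector for one (species, sub-area, year) slice."""

    species: str
    sub_area: str
    year: int
    cg_x: float
    cg_y: float
    cg_lon: float
    cg_lat: float
    inertia: float
    isotropy: float
    n_major_patches: int
    positive_area: float
    spreading_area: float
    equivalent_area: float
    biomass: float
    packing_density: float

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def compute_indicator_set(dataset: SurveyDataset, species: str,
                          sub_area: str | None = None, year: int | None = None,
                          dlim: float = 20.0, min_fraction: float = 0.10) -> IndicatorSet:
    """Assemble all indicators for one (species, sub-area, year) slice.

    The dataset must already be filtered to a single slice with at least
    one positive sample.
    """
    x, y = dataset.xy()
    z = dataset.density(species)
    s = dataset.area_influence
    if sub_area is None:
        sub_area = str(dataset.data["sub_area"].iloc[0])
    if year is None:
        year = int(dataset.data["survey_year"].iloc[0])
    cgx, cgy = centre_of_gravity(x, y, z, s)
    origin = dataset.origin
    if origin is None:
        raise ValueError("dataset has no projection origin; project first")
    cglon, cglat = inverse_project(np.array([cgx]), np.array([cgy]), origin)
    inertia, isotropy, _ = inertia_and_isotropy(x, y, z, s)
    pa = positive_area(z, s)
    q = estimate_biomass(dataset, species, "edsu")
    return IndicatorSet(
        species=species, sub_area=sub_area, year=year,
        cg_x=cgx, cg_y=cgy, cg_lon=float(cglon[0]), cg_lat=float(cglat[0]),
        inertia=inertia, isotropy=isotropy,
        n_major_patches=identify_patches(x, y, z, s, dlim, min_fraction).n_major,
        positive_area=pa,
        spreading_area=spreading_area(z, s),
        equivalent_area=equivalent_area(z, s),
        biomass=q,
        packing_density=packing_density(q, pa),
    )


def compute_indicator_table(dataset: SurveyDataset, species: list[str] | None = None,
                            group_keys: tuple[str, ...] = ("survey_year", "sub_area"),
                            dlim: float = 20.0, min_fraction: float = 0.10,
                            with_gic: bool = True) -> pd.DataFrame:
    """Indicator table over all (species, group) slices of a dataset.

    With ``with_gic`` and exactly two species, each row additionally carries
    the global index of collocation between the two species in its group.
    Slices with zero abundance are skipped.
    """
    ds = dataset if dataset.has_projection else None
    if ds is None:
        from .survey import project_coordinates
        ds = project_coordinates(dataset)
    species = list(species or ds.species)
    rows = []
    for keys, sub in ds.data.groupby(list(group_keys), sort=True):
        sub_ds = SurveyDataset(sub.reset_index(drop=True), ds.species, origin=ds.origin)
        gic = np.nan
        if with_gic and len(species) == 2:
            pops = []
            for sp in species:
                zz = sub_ds.density(sp)
                pops.append((sub_ds.data["x"], sub_ds.data["y"], zz, sub_ds.area_influence))
            try:
                gic = global_index_of_collocation(pops[0], pops[1])
            except UndefinedIndicatorError:
                gic = np.nan
        for sp in species:
            try:
                ind = compute_indicator_set(sub_ds, sp, dlim=dlim, min_fraction=min_fraction)
            except UndefinedIndicatorError:
                continue
            row = ind.as_row()
            row["gic"] = gic
            rows.append(row)
    return pd.DataFrame(rows)
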