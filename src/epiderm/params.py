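"""Default cohort parameters and configuration types.

The synthetic-cohort generator is parameterized per facial site and per age
group.  The default values below are the published summary statistics of a
100-volunteer facial-ageing study (temple, cheekbone, mandible; five 10-year
age groups between 20 and 70): layer thicknesses and DEJ undulation, cell
layer counts, and per-maturation-band cellular metrics.  Each entry is a
``(mean, sd)`` pair; for the band metrics two dispersion levels exist (the
between-subject sd of the subject mean, and the within-subject sd which the
study reports as its own metric).

All lengths are um, volumes um^3, densities cells/mm^2, undulation percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from hashlib import blake2b
from typing import Mapping, Optional, Sequence

__all__ = [
    "SITES",
    "AGE_GROUPS",
    "BANDS",
    "BandParams",
    "SubjectParams",
    "CohortConfig",
    "default_subject_params",
    "default_cohort_config",
    "subject_seed",
    "LAYER_TABLE",
    "LAYER_COUNT_TABLE",
    "CELL_TABLE",
]

SITES = ("temple", "cheekbone", "mandible")
AGE_GROUPS = ("[20,30]", "[31,40]", "[41,50]", "[51,60]", "[61,70]")
#: Maturation bands: quintiles of normalized depth within the viable
#: epidermis. M1 is the deepest 20% (stratum basale side), M5 the most
#: superficial 20% (stratum granulosum side).
BANDS = ("M1", "M2", "M3", "M4", "M5")

# --- Layer metrics: SC thickness, VE thickness, %U_DEJ -----------------------
# (mean, sd) per age group, in AGE_GROUPS order.
LAYER_TABLE = {
    "temple": {
        "sc": [(13.2, 0.8), (13.4, 0.8), (13.4, 1.2), (13.6, 0.9), (14.2, 1.0)],
        "ve": [(54.6, 6.8), (53.3, 4.6), (51.4, 3.9), (53.0, 4.9), (52.1, 4.8)],
        "undulation": [(2.64, 2.04), (2.31, 1.76), (2.12, 1.88), (2.42, 1.96), (2.07, 1.26)],
    },
    "cheekbone": {
        "sc": [(12.1, 0.5), (12.4, 0.5), (12.5, 0.9), (12.3, 0.6), (12.5, 0.8)],
        "ve": [(48.4, 6.5), (49.0, 6.6), (44.7, 7.8), (46.8, 6.1), (45.7, 7.4)],
        "undulation": [(0.26, 0.39), (0.46, 0.56), (0.37, 0.42), (0.475, 0.457), (0.48, 0.48)],
    },
    "mandible": {
        "sc": [(13.1, 0.4), (13.3, 1.0), (13.4, 0.8), (13.6, 0.8), (13.9, 1.3)],
        "ve": [(55.1, 7.2), (57.5, 8.2), (51.0, 4.6), (50.5, 6.4), (48.1, 5.3)],
        "undulation": [(1.44, 1.66), (1.19, 1.13), (1.42, 1.52), (1.44, 1.04), (1.08, 0.84)],
    },
}

# --- Cell layer counts -------------------------------------------------------
# "layers": subject-mean number of cell layers in the VE (mean, sd across
# subjects); "layers_sd": within-subject sd of the local (tile) layer count,
# itself summarized as (mean, sd across subjects).
LAYER_COUNT_TABLE = {
    "temple": {
        "layers": [(6.16, 0.58), (6.02, 0.48), (5.86, 0.56), (5.88, 0.57), (5.87, 0.50)],
        "layers_sd": [(1.28, 0.18), (1.24, 0.11), (1.17, 0.09), (1.21, 0.11), (1.14, 0.12)],
    },
    "cheekbone": {
        "layers": [(5.37, 0.63), (5.59, 0.71), (5.25, 0.80), (5.34, 0.51), (5.37, 0.75)],
        "layers_sd": [(1.10, 0.14), (1.10, 0.16), (1.01, 0.11), (1.06, 0.12), (1.03, 0.13)],
    },
    "mandible": {
        "layers": [(6.28, 0.65), (6.39, 0.61), (6.04, 0.52), (5.76, 0.65), (5.64, 0.57)],
        "layers_sd": [(1.19, 0.12), (1.22, 0.13), (1.11, 0.14), (1.10, 0.13), (1.05, 0.11)],
    },
}

# --- Per-band cellular metrics ----------------------------------------------
# Rows are age groups (AGE_GROUPS order), columns are bands in M5..M1 order as
# printed in the source tables; reordered to M1..M5 when building the config.
# csd: cell surface density; nv: subject-mean nucleus volume; std_nv:
# within-subject sd of nucleus volume; nc: subject-mean nucleus compactness
# (sphericity); std_c: within-subject sd of compactness; cna: cell network
# atypia (flagged outlier fraction).
_M5_TO_M1 = ("M5", "M4", "M3", "M2", "M1")

_CELL_RAW = {
    "temple": {
        "csd": [
            [(2934, 195), (5368, 365), (5919, 481), (4851, 551), (2996, 507)],
            [(2823, 167), (5092, 398), (5717, 547), (4787, 605), (2975, 546)],
            [(2731, 176), (4945, 455), (5737, 634), (4910, 647), (2998, 537)],
            [(2743, 165), (4886, 404), (5453, 565), (4553, 559), (2787, 351)],
            [(2580, 174), (4729, 382), (5396, 387), (4584, 549), (2903, 489)],
        ],
        "nv": [
            [(208, 17), (155, 13), (133, 6), (127, 4), (127, 7)],
            [(209, 13), (162, 12), (137, 6), (129, 4), (130, 7)],
            [(219, 14), (169, 17), (139, 9), (130, 6), (131, 7)],
            [(208, 18), (163, 19), (138, 10), (130, 6), (132, 8)],
            [(220, 28), (166, 25), (138, 11), (132, 6), (135, 9)],
        ],
        "std_nv": [
            [(96.9, 6.2), (63.2, 7.7), (54.1, 6.2), (54.7, 7.2), (59.2, 9.2)],
            [(95.2, 7.2), (60.5, 4.3), (53.9, 4.2), (56.7, 5.3), (59.7, 8.3)],
            [(94.6, 6.7), (63.1, 4.3), (54.3, 4.0), (55.5, 6.9), (58.8, 8.2)],
            [(99.3, 7.0), (66.0, 6.6), (55.0, 4.0), (56.0, 5.2), (60.4, 7.1)],
            [(96.3, 8.7), (65.6, 8.6), (56.5, 6.0), (57.7, 6.9), (61.6, 8.7)],
        ],
        "nc": [
            [(0.671, 0.029), (0.757, 0.015), (0.801, 0.012), (0.810, 0.012), (0.805, 0.014)],
            [(0.671, 0.031), (0.753, 0.016), (0.799, 0.010), (0.810, 0.010), (0.805, 0.011)],
            [(0.659, 0.028), (0.742, 0.021), (0.793, 0.014), (0.809, 0.011), (0.806, 0.014)],
            [(0.681, 0.028), (0.757, 0.018), (0.799, 0.009), (0.810, 0.008), (0.809, 0.009)],
            [(0.683, 0.026), (0.760, 0.013), (0.801, 0.011), (0.814, 0.010), (0.813, 0.010)],
        ],
        "std_c": [
            [(0.106, 0.004), (0.082, 0.004), (0.068, 0.004), (0.066, 0.006), (0.070, 0.007)],
            [(0.107, 0.005), (0.084, 0.005), (0.068, 0.004), (0.066, 0.004), (0.070, 0.005)],
            [(0.107, 0.004), (0.085, 0.007), (0.070, 0.005), (0.067, 0.004), (0.070, 0.006)],
            [(0.106, 0.005), (0.083, 0.007), (0.069, 0.005), (0.066, 0.004), (0.069, 0.005)],
            [(0.107, 0.005), (0.083, 0.005), (0.068, 0.005), (0.065, 0.005), (0.067, 0.005)],
        ],
        "cna": [
            [(0.115, 0.017), (0.116, 0.025), (0.153, 0.028), (0.200, 0.039), (0.231, 0.027)],
            [(0.124, 0.025), (0.129, 0.023), (0.168, 0.022), (0.197, 0.020), (0.228, 0.022)],
            [(0.130, 0.031), (0.154, 0.042), (0.200, 0.049), (0.217, 0.038), (0.240, 0.027)],
            [(0.141, 0.030), (0.153, 0.051), (0.187, 0.059), (0.225, 0.043), (0.249, 0.027)],
            [(0.152, 0.044), (0.169, 0.057), (0.199, 0.048), (0.235, 0.035), (0.256, 0.035)],
        ],
    },
    "cheekbone": {
        "csd": [
            [(2881, 135), (5065, 267), (5897, 335), (5269, 344), (3347, 396)],
            [(2891, 157), (4992, 346), (5896, 409), (5431, 437), (3553, 528)],
            [(2803, 171), (4816, 486), (5813, 517), (5494, 459), (3802, 581)],
            [(2794, 166), (4834, 340), (5813, 346), (5436, 551), (3669, 695)],
            [(2701, 167), (4714, 316), (5738, 418), (5497, 627), (3714, 616)],
        ],
        "nv": [
            [(223, 17), (176, 16), (149, 10), (134, 5), (130, 4)],
            [(224, 19), (180, 16), (149, 11), (132, 5), (129, 6)],
            [(218, 21), (176, 19), (148, 13), (135, 8), (132, 6)],
            [(227, 24), (179, 19), (151, 13), (135, 6), (131, 5)],
            [(236, 30), (185, 24), (154, 13), (139, 7), (134, 7)],
        ],
        "std_nv": [
            [(96.9, 6.2), (63.2, 7.7), (54.1, 6.2), (54.7, 7.2), (59.2, 9.2)],
            [(98.8, 5.8), (67.3, 6.6), (57.4, 5.7), (54.8, 3.8), (57.3, 6.4)],
            [(98.7, 9.0), (67.1, 5.3), (56.3, 4.8), (53.7, 4.3), (57.7, 6.8)],
            [(99.2, 9.2), (69.2, 7.7), (58.2, 5.4), (56.9, 4.6), (60.9, 7.8)],
            [(101.8, 12.4), (69.2, 7.1), (58.7, 4.6), (56.5, 5.1), (59.9, 7.1)],
        ],
        "nc": [
            [(0.638, 0.033), (0.735, 0.021), (0.793, 0.012), (0.813, 0.009), (0.814, 0.011)],
            [(0.635, 0.039), (0.727, 0.023), (0.789, 0.012), (0.812, 0.008), (0.812, 0.012)],
            [(0.632, 0.025), (0.717, 0.018), (0.775, 0.016), (0.799, 0.016), (0.800, 0.018)],
            [(0.631, 0.025), (0.718, 0.020), (0.778, 0.013), (0.803, 0.012), (0.804, 0.015)],
            [(0.620, 0.037), (0.706, 0.029), (0.768, 0.018), (0.797, 0.012), (0.802, 0.010)],
        ],
        "std_c": [
            [(0.111, 0.004), (0.090, 0.004), (0.071, 0.004), (0.064, 0.004), (0.067, 0.006)],
            [(0.111, 0.004), (0.091, 0.006), (0.072, 0.005), (0.064, 0.003), (0.069, 0.007)],
            [(0.111, 0.006), (0.092, 0.006), (0.076, 0.006), (0.069, 0.006), (0.073, 0.008)],
            [(0.111, 0.006), (0.094, 0.006), (0.075, 0.006), (0.068, 0.005), (0.071, 0.007)],
            [(0.111, 0.005), (0.095, 0.007), (0.079, 0.006), (0.071, 0.004), (0.073, 0.005)],
        ],
        "cna": [
            [(0.115, 0.017), (0.158, 0.024), (0.226, 0.038), (0.249, 0.037), (0.245, 0.024)],
            [(0.116, 0.021), (0.152, 0.031), (0.205, 0.039), (0.227, 0.033), (0.230, 0.021)],
            [(0.124, 0.030), (0.173, 0.062), (0.235, 0.067), (0.257, 0.058), (0.257, 0.059)],
            [(0.124, 0.024), (0.169, 0.033), (0.235, 0.047), (0.257, 0.041), (0.248, 0.024)],
            [(0.143, 0.035), (0.203, 0.066), (0.267, 0.065), (0.279, 0.040), (0.260, 0.028)],
        ],
    },
    "mandible": {
        "csd": [
            [(2787, 149), (5276, 289), (6135, 402), (5213, 497), (3092, 537)],
            [(2697, 156), (4998, 336), (6027, 399), (5351, 530), (3346, 684)],
            [(2631, 145), (4831, 408), (6028, 401), (5549, 530), (3529, 705)],
            [(2604, 165), (4642, 338), (5569, 370), (5058, 518), (3254, 580)],
            [(2519, 177), (4560, 394), (5686, 396), (5299, 448), (3397, 580)],
        ],
        "nv": [
            [(220, 17), (165, 18), (139, 12), (129, 8), (128, 7)],
            [(235, 23), (181, 19), (145, 13), (130, 6), (126, 7)],
            [(237, 16), (183, 16), (145, 10), (131, 6), (130, 4)],
            [(225, 22), (180, 24), (145, 11), (132, 5), (130, 7)],
            [(245, 25), (189, 28), (148, 15), (133, 6), (132, 6)],
        ],
        "std_nv": [
            [(96.9, 6.2), (63.2, 7.7), (54.1, 6.2), (54.7, 7.2), (59.2, 9.2)],
            [(100.0, 8.8), (66.9, 6.2), (54.1, 4.8), (51.3, 3.4), (54.0, 6.5)],
            [(105.8, 9.7), (70.9, 6.3), (56.3, 4.8), (55.6, 4.1), (59.8, 5.2)],
            [(101.3, 9.6), (70.8, 8.8), (57.8, 4.4), (56.6, 5.9), (60.3, 10.3)],
            [(112.6, 17.2), (75.7, 11.6), (59.2, 6.0), (57.3, 5.0), (61.6, 6.5)],
        ],
        "nc": [
            [(0.650, 0.027), (0.744, 0.017), (0.799, 0.016), (0.812, 0.016), (0.808, 0.018)],
            [(0.644, 0.026), (0.736, 0.016), (0.793, 0.012), (0.813, 0.010), (0.813, 0.013)],
            [(0.642, 0.023), (0.720, 0.028), (0.779, 0.019), (0.805, 0.010), (0.805, 0.009)],
            [(0.659, 0.026), (0.734, 0.022), (0.784, 0.013), (0.805, 0.010), (0.807, 0.012)],
            [(0.654, 0.026), (0.730, 0.020), (0.784, 0.011), (0.806, 0.008), (0.807, 0.008)],
        ],
        "std_c": [
            [(0.106, 0.004), (0.084, 0.005), (0.068, 0.005), (0.064, 0.006), (0.068, 0.008)],
            [(0.107, 0.004), (0.086, 0.005), (0.070, 0.004), (0.064, 0.003), (0.066, 0.006)],
            [(0.108, 0.005), (0.088, 0.008), (0.074, 0.007), (0.067, 0.004), (0.071, 0.005)],
            [(0.109, 0.008), (0.088, 0.007), (0.074, 0.006), (0.068, 0.005), (0.070, 0.007)],
            [(0.109, 0.007), (0.090, 0.008), (0.074, 0.005), (0.067, 0.003), (0.070, 0.004)],
        ],
        "cna": [
            [(0.106, 0.017), (0.123, 0.028), (0.169, 0.044), (0.205, 0.044), (0.233, 0.036)],
            [(0.117, 0.023), (0.154, 0.043), (0.196, 0.048), (0.205, 0.037), (0.222, 0.025)],
            [(0.128, 0.024), (0.167, 0.055), (0.203, 0.062), (0.225, 0.042), (0.237, 0.023)],
            [(0.139, 0.030), (0.176, 0.056), (0.218, 0.057), (0.229, 0.045), (0.236, 0.027)],
            [(0.162, 0.074), (0.204, 0.086), (0.241, 0.073), (0.243, 0.043), (0.241, 0.018)],
        ],
    },
}

#: CELL_TABLE[site][band][group][metric] -> (mean, sd)
CELL_TABLE: dict = {}
for _site, _metrics in _CELL_RAW.items():
    CELL_TABLE[_site] = {b: {g: {} for g in AGE_GROUPS} for b in BANDS}
    for _metric, _rows in _metrics.items():
        for _gi, _group in enumerate(AGE_GROUPS):
            for _bi, _band in enumerate(_M5_TO_M1):
                CELL_TABLE[_site][_band][_group][_metric] = _rows[_gi][_bi]


# --- Parameter dataclasses ---------------------------------------------------

@dataclass
class BandParams:
    """Generator parameters for one maturation band.

    Subject-level quantities (the per-subject CSD target, the subject-mean
    nucleus volume/compactness, the within-subject sds and the atypical
    fraction) are drawn from Normal distributions truncated at +/-3 sd with
    the ``*_sd`` fields as spread; per-nucleus volumes are then drawn
    log-normally with the subject's (mean, within-sd), and compactness
    normally, so positivity and the (0, 1] range are respected.
    """

    csd_mean: float
    csd_sd: float
    nv_mean: float
    nv_between_sd: float
    nv_within_mean: float
    nv_within_sd: float
    nc_mean: float
    nc_between_sd: float
    nc_within_mean: float
    nc_within_sd: float
    atypical_mean: float = 0.0
    atypical_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.csd_mean < 0:
            raise ValueError("csd_mean must be >= 0")
        if self.nv_mean <= 0:
            raise ValueError("nv_mean must be > 0")
        if not (0 < self.nc_mean <= 1):
            raise ValueError("nc_mean must lie in (0, 1]")
        if not (0 <= self.atypical_mean <= 1):
            raise ValueError("atypical_mean must lie in [0, 1]")


@dataclass
class SubjectParams:
    """Group-level generator parameters for one (site, age-group) cell.

    A concrete subject is realized by drawing from these distributions with
    the subject's ``seed``; two subjects with the same params but different
    seeds are independent draws from the same cohort cell.
    """

    sc_thickness_mean: float
    sc_thickness_sd: float
    ve_thickness_mean: float
    ve_thickness_sd: float
    dej_undulation_mean: float
    dej_undulation_sd: float
    n_layers_mean: float
    n_layers_sd: float
    layer_sd_mean: float
    layer_sd_sd: float
    bands: dict[str, BandParams] = field(default_factory=dict)
    atypical_volume_factor: float = 3.0
    dej_correlation_length: float = 50.0
    patch_size: float = 50.0
    seed: Optional[int] = None
    site: str = ""
    age_group: str = ""

    def __post_init__(self) -> None:
        if self.sc_thickness_mean <= 0 or self.ve_thickness_mean <= 0:
            raise ValueError("thickness means must be positive")
        if self.sc_thickness_sd < 0 or self.ve_thickness_sd < 0:
            raise ValueError("thickness sds must be >= 0")
        if self.dej_undulation_mean < 0:
            raise ValueError("dej_undulation_mean must be >= 0")
        if self.n_layers_mean < 1:
            raise ValueError("n_layers_mean must be >= 1")
        if self.dej_correlation_length <= 0 or self.patch_size <= 0:
            raise ValueError("length scales must be positive")
        for name, bp in self.bands.items():
            if name not in BANDS:
                raise ValueError(f"unknown band {name!r}")
            if not isinstance(bp, BandParams):
                raise TypeError("bands values must be BandParams")

    def replace(self, **kw) -> "SubjectParams":
        d = {**self.__dict__, **kw}
        return SubjectParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubjectParams":
        d = dict(d)
        d["bands"] = {k: BandParams(**v) for k, v in d.get("bands", {}).items()}
        return cls(**d)


def default_subject_params(site: str, age_group: str, seed: Optional[int] = None) -> SubjectParams:
    """Generator parameters for a (site, age group) cell from the default tables."""
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; expected one of {SITES}")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}; expected one of {AGE_GROUPS}")
    gi = AGE_GROUPS.index(age_group)
    lay = LAYER_TABLE[site]
    cnt = LAYER_COUNT_TABLE[site]
    bands = {}
    for band in BANDS:
        cell = CELL_TABLE[site][band][age_group]
        bands[band] = BandParams(
            csd_mean=cell["csd"][0],
            csd_sd=cell["csd"][1],
            nv_mean=cell["nv"][0],
            nv_between_sd=cell["nv"][1],
            nv_within_mean=cell["std_nv"][0],
            nv_within_sd=cell["std_nv"][1],
            nc_mean=cell["nc"][0],
            nc_between_sd=cell["nc"][1],
            nc_within_mean=cell["std_c"][0],
            nc_within_sd=cell["std_c"][1],
            atypical_mean=cell["cna"][0],
            atypical_sd=cell["cna"][1],
        )
    return SubjectParams(
        sc_thickness_mean=lay["sc"][gi][0],
        sc_thickness_sd=lay["sc"][gi][1],
        ve_thickness_mean=lay["ve"][gi][0],
        ve_thickness_sd=lay["ve"][gi][1],
        dej_undulation_mean=lay["undulation"][gi][0],
        dej_undulation_sd=lay["undulation"][gi][1],
        n_layers_mean=cnt["layers"][gi][0],
        n_layers_sd=cnt["layers"][gi][1],
        layer_sd_mean=cnt["layers_sd"][gi][0],
        layer_sd_sd=cnt["layers_sd"][gi][1],
        bands=bands,
        seed=seed,
        site=site,
        age_group=age_group,
    )


@dataclass
class CohortConfig:
    """A cohort: sites x age groups x subjects, plus the master seed."""

    sites: Sequence[str] = SITES
    age_groups: Sequence[str] = AGE_GROUPS
    subjects_per_group: int = 20
    params: dict = field(default_factory=dict)  # (site, group) -> SubjectParams
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        self.age_groups = tuple(self.age_groups)
        if self.subjects_per_group < 2:
            raise ValueError("subjects_per_group must be >= 2")
        if not self.params:
            self.params = {
                (s, g): default_subject_params(s, g)
                for s in self.sites
                for g in self.age_groups
            }

    @property
    def n_subjects(self) -> int:
        return len(self.sites) * len(self.age_groups) * self.subjects_per_group

    def to_dict(self) -> dict:
        return {
            "sites": list(self.sites),
            "age_groups": list(self.age_groups),
            "subjects_per_group": self.subjects_per_group,
            "master_seed": self.master_seed,
            "params": {
                f"{s}|{g}": p.to_dict() for (s, g), p in sorted(self.params.items())
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        params = {}
        for key, pd in d.get("params", {}).items():
            s, g = key.split("|")
            params[(s, g)] = SubjectParams.from_dict(pd)
        return cls(
            sites=d.get("sites", SITES),
            age_groups=d.get("age_groups", AGE_GROUPS),
            subjects_per_group=d.get("subjects_per_group", 20),
            params=params,
            master_seed=d.get("master_seed", 0),
        )


def default_cohort_config(
    subjects_per_group: int = 20,
    sites: Sequence[str] = SITES,
    age_groups: Sequence[str] = AGE_GROUPS,
    master_seed: int = 0,
) -> CohortConfig:
    return CohortConfig(
        sites=sites,
        age_groups=age_groups,
        subjects_per_group=subjects_per_group,
        master_seed=master_seed,
    )


def subject_seed(master_seed: int, site: str, age_group: str, index: int) -> int:
    """Stable per-subject seed: hash of (master seed, site, group, index).

    Kept below 2**31 so it can feed any downstream RNG or be serialized
    losslessly to JSON in 32-bit contexts.
    """
    key = f"{master_seed}|{site}|{age_group}|{index}".encode()
    return int.from_bytes(blake2b(key, digest_size=4).digest(), "big") % (2**31)
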