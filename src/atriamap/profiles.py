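"""Default atrial SR/AF study profile: marker panels, composition, reference numbers.

The packaged defaults emulate the single-cell landscape of human right-atrial
appendage tissue in sinus rhythm (SR) versus atrial fibrillation (AF): eight
major cell types — fibroblasts (FB), smooth muscle cells (SMC), endothelial
cells (EC), atrial cardiomyocytes (aCM), myeloid (My), lymphoid (Ly),
epicardial and neuronal cells — partitioned into 23 subclusters, with the
reported pooled major-type proportions (44% FB, 27.3% immune, 14.6% EC, 8.1%
SMC, 3.2% aCM, 1.5% epicardial, 1.2% neuronal) and the marker genes reported
for the FB/SMC/EC subclusters.

Markers for the immune, cardiomyocyte, epicardial and neuronal subclusters are
not enumerated in that study; the defaults below use standard cardiac-atlas
markers for those compartments and are explicitly overridable.  Gene symbols
are uppercase HGNC-style throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from ._utils import ConfigError

#: Summary numbers reported by the atrial SR/AF study the defaults emulate.
#: These are reference metadata, not quantities this package computes.
REPORTED = {
    "cells_sr": 37_450,
    "cells_af": 33_990,
    "cells_total": 71_440,
    "major_pct": {
        "FB": 44.0,
        "immune": 27.3,
        "EC": 14.6,
        "SMC": 8.1,
        "aCM": 3.2,
        "Epicardial": 1.5,
        "Neuronal": 1.2,
    },
    "n_major_types": 8,
    "n_subclusters": 23,
    "n_patterns": 14,
    "n_deg_universe": 1791,
    "n_gwas_genes": 281,
    "n_diff_proteins": 625,
    "n_gwas_overlap": 42,
    "n_protein_overlap": 139,
}


@dataclass(frozen=True)
class MarkerPanel:
    """Marker genes per major cell type and per subcluster.

    ``major`` maps each major type to its identifying genes; ``sub`` maps each
    major type to an ordered mapping subcluster -> marker genes.  Type order is
    meaningful: it is the declared tie-break order for type assignment.
    """

    major: Mapping[str, tuple[str, ...]]
    sub: Mapping[str, Mapping[str, tuple[str, ...]]]

    def validate(self) -> None:
        if not self.major:
            raise ConfigError("marker panel has no major types")
        for typ, genes in self.major.items():
            if len(genes) == 0:
                raise ConfigError(f"major type {typ!r} has an empty marker list")
            for g in genes:
                if not g or g != g.upper():
                    raise ConfigError(f"marker symbol {g!r} for {typ!r} must be non-blank uppercase")
        for typ, subs in self.sub.items():
            if typ not in self.major:
                raise ConfigError(f"subcluster panel references unknown major type {typ!r}")
            for sc, genes in subs.items():
                if len(genes) == 0:
                    raise ConfigError(f"subcluster {sc!r} has an empty marker list")
                for g in genes:
                    if not g or g != g.upper():
                        raise ConfigError(f"marker symbol {g!r} for {sc!r} must be non-blank uppercase")

    @property
    def major_order(self) -> tuple[str, ...]:
        return tuple(self.major.keys())

    @property
    def sub_flat(self) -> dict[str, tuple[str, ...]]:
        """Flat subcluster -> markers mapping across all major types."""
        out: dict[str, tuple[str, ...]] = {}
        for subs in self.sub.values():
            for sc, genes in subs.items():
                out[sc] = tuple(genes)
        return out

    def parent_of(self, subcluster: str) -> str:
        for typ, subs in self.sub.items():
            if subcluster in subs:
                return typ
        raise KeyError(f"subcluster {subcluster!r} not in panel")

    def subclusters_of(self, major: str) -> tuple[str, ...]:
        return tuple(self.sub.get(major, {}).keys())

    def k_map(self) -> dict[str, int]:
        """Default per-type subcluster count (number of sub-panel entries)."""
        return {typ: max(1, len(self.sub.get(typ, {}))) for typ in self.major}

    def all_genes(self) -> list[str]:
        """All panel genes, deduplicated, in declaration order."""
        seen: dict[str, None] = {}
        for genes in self.major.values():
            for g in genes:
                seen.setdefault(g)
        for subs in self.sub.values():
            for genes in subs.values():
                for g in genes:
                    seen.setdefault(g)
        return list(seen)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "major": {t: list(g) for t, g in self.major.items()},
            "sub": {t: {s: list(g) for s, g in subs.items()} for t, subs in self.sub.items()},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        panel = cls(
            major={t: tuple(g) for t, g in data["major"].items()},
            sub={t: {s: tuple(g) for s, g in subs.items()} for t, subs in data.get("sub", {}).items()},
        )
        panel.validate()
        return panel


# Reported markers for FB/SMC/EC compartments; atlas-standard markers for the
# compartments whose panels the study does not print (aCM/My/Ly subclusters,
# epicardial, neuronal) — placeholders by design, overridable via config.
DEFAULT_PANEL = MarkerPanel(
    major={
        "FB": ("DCN", "GSN"),
        "SMC": ("MYH11", "TAGLN", "MYL9", "ACTA2"),
        "aCM": ("MYL7", "NPPA"),
        "EC": ("VWF", "PECAM1"),
        "My": ("TYROBP", "CD74", "HLA-DRA"),
        "Ly": ("PTPRC", "CXCR4"),
        "Epicardial": ("MSLN", "WT1", "BNC1"),
        "Neuronal": ("PLP1", "NRXN1", "S100B"),
    },
    sub={
        "FB": {
            "FB1": ("PEAK1", "SMAD4"),
            "FB2": ("CXCL2", "CXCL14", "IL6"),
            "FB3": ("AEBP1", "COL1A1", "COL3A1"),
            "FB4": ("APOE", "PTGDS"),
            "FB5": ("IGFBP6", "MFAP5"),
            "FB6": ("ABCA6", "ABCA10"),
        },
        "SMC": {
            "SMC1": ("MYH11",),
            "SMC2": ("CD36", "TXNIP", "FABP4", "ABCC9", "RGS5"),
        },
        "EC": {
            "EC1": ("NPR3", "LEPR", "COLEC11"),
            "EC2": ("CCL14", "SELE", "IL6"),
            "EC3": ("DST", "IGFBP3", "RHOB"),
        },
        "aCM": {
            "aCM1": ("MYL4", "TNNT2"),
            "aCM2": ("NPPB", "MYH6"),
        },
        "My": {
            "My1": ("LYZ", "S100A8"),
            "My2": ("C1QA", "C1QB"),
            "My3": ("FCN1", "VCAN"),
            "My4": ("CD1C", "FCER1A"),
        },
        "Ly": {
            "Ly1": ("CD3D", "IL7R"),
            "Ly2": ("NKG7", "GNLY"),
            "Ly3": ("CD79A", "MS4A1"),
            "Ly4": ("GZMK", "CCL5"),
        },
        "Epicardial": {"Epi1": ("MSLN", "UPK3B")},
        "Neuronal": {"Neu1": ("PLP1", "NRXN3")},
    },
)

# Pooled major-type fractions.  The printed percentages sum to 99.9%, so they
# are renormalised; the 27.3% immune compartment is split My:Ly = 60:40 (the
# split is not printed anywhere).
_PRINTED_MAJOR = {
    "FB": 0.440,
    "My": 0.273 * 0.6,
    "Ly": 0.273 * 0.4,
    "EC": 0.146,
    "SMC": 0.081,
    "aCM": 0.032,
    "Epicardial": 0.015,
    "Neuronal": 0.012,
}
_PRINTED_TOTAL = sum(_PRINTED_MAJOR.values())  # 0.999

# AF-minus-SR shift per subcluster (sums to zero): FB3 (and mildly FB1/FB5)
# and My up in AF; aCM, EC and epicardial down — the reported direction of the
# condition composition change.  Magnitudes are package choices; none are
# printed.
_AF_SHIFT = {
    "FB1": +0.002,
    "FB2": -0.004,
    "FB3": +0.040,
    "FB4": -0.004,
    "FB5": +0.002,
    "FB6": -0.004,
    "My1": +0.003,
    "My2": +0.003,
    "My3": +0.003,
    "My4": +0.003,
    "aCM1": -0.004,
    "aCM2": -0.004,
    "EC1": -0.010,
    "EC2": -0.010,
    "EC3": -0.010,
    "Epi1": -0.006,
}


def default_composition() -> dict[str, tuple[str, float, float]]:
    """Packaged composition profile: subcluster -> (major, frac_SR, frac_AF).

    Within each major type the pooled fraction is split uniformly across its
    subclusters (per-subcluster fractions are not printed), then tilted by
    ±shift/2 per condition so that the SR/AF mean equals the pooled target
    exactly.
    """
    comp: dict[str, tuple[str, float, float]] = {}
    for major, frac in _PRINTED_MAJOR.items():
        subs = DEFAULT_PANEL.subclusters_of(major)
        f = frac / _PRINTED_TOTAL / len(subs)
        for sc in subs:
            d = _AF_SHIFT.get(sc, 0.0)
            comp[sc] = (major, f - d / 2.0, f + d / 2.0)
    return comp


#: Condition-dependent genes planted in the default profile: the reported
#: FB3 AF-vs-SR signature (collagen/ECM genes up, metallothioneins down) and
#: the EC1 fibrosis mediators.  log2 fold changes are package choices.
DEFAULT_CONDITION_DE: tuple[tuple[str, str, float], ...] = (
    ("COL3A1", "FB3", 2.0),
    ("ELN", "FB3", 1.5),
    ("SPARC", "FB3", 1.0),
    ("TPM1", "FB3", 1.0),
    ("ACTA2", "FB3", 1.0),
    ("MT2A", "FB3", -1.5),
    ("MT1X", "FB3", -1.0),
    ("TXNDC5", "EC1", 1.0),
    ("POSTN", "EC1", 1.0),
)
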