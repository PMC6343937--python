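"""Registry of the mouse/human inflammatory-pathology cohorts and the
enumeration rule that turns them into translation case studies.

A *case study* pairs one mouse training unit with one human test unit for
the same disease.  Units are derived from the cohort catalog by fixed
partitioning rules:

* human cohorts split into one unit per microarray platform;
* mouse cohorts split into one unit per disease-induction arm and per
  strain, and multi-strain cohorts additionally contribute a combined
  (all-strains) unit.

Applied to the catalog below (burn, trauma, endotoxemia and sepsis cohorts
in whole blood / leukocytes), the rule yields exactly 36 case studies.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class HumanCohort:
    disease: str
    accession: str
    platforms: tuple[str, ...]
    n_control: int
    n_disease: int
    tissue: str = ""


@dataclass(frozen=True)
class MouseCohort:
    disease: str
    accession: str
    induction: str                   # e.g. "LPS", "CLP", "SPS2", "SA"
    arms: tuple[str, ...]            # disease arms beyond control
    strains: tuple[str, ...]
    n_control: int
    n_disease_per_arm: tuple[int, ...]
    tissue: str = ""


HUMAN_COHORTS: tuple[HumanCohort, ...] = (
    HumanCohort("Burn", "GSE37069", ("GPL570",), 37, 553, "White Blood Cells"),
    HumanCohort("Trauma", "GSE36809", ("GPL570",), 37, 216, "White Blood Cells"),
    HumanCohort("Endotoxemia", "GSE3284", ("GPL96", "GPL97"), 16, 76, "Whole Blood"),
    HumanCohort("Sepsis", "GSE13904", ("GPL570",), 18, 158, "Whole Blood"),
    HumanCohort("Sepsis", "GSE9960", ("GPL570",), 16, 54, "PBMC"),
    HumanCohort("Sepsis", "GSE28750", ("GPL570",), 20, 21, "Whole Blood"),
    HumanCohort("Sepsis", "GSE13015", ("GPL6947", "GPL6106"), 29, 77, "Whole Blood"),
)

MOUSE_COHORTS: tuple[MouseCohort, ...] = (
    MouseCohort("Burn", "GSE7404", "Burn", ("Burn",), ("C57BL/6J",),
                16, (16,), "Leukocytes"),
    MouseCohort("Trauma", "GSE7404", "Trauma", ("Trauma",), ("C57BL/6J",),
                16, (16,), "Leukocytes"),
    MouseCohort("Endotoxemia", "GSE7404", "LPS", ("Endotoxemia",),
                ("C57BL/6J",), 8, (8,), "Leukocytes"),
    MouseCohort("Endotoxemia", "GSE5663", "LPS", ("Endotoxemia",),
                ("C57BL/6J",), 4, (5,), "Blood"),
    MouseCohort("Sepsis", "GSE5663", "CLP", ("Mild Sepsis", "Sepsis"),
                ("C57BL/6J",), 4, (5, 5), "Blood"),
    MouseCohort("Sepsis", "GSE26472", "SPS2", ("Sepsis",), ("C57BL/6J",),
                3, (8,), "Blood"),
    MouseCohort("Sepsis", "GSE19668", "SA", ("Sepsis",), ("A/J", "C57BL/6J"),
                10, (40,), "Blood"),
)


@dataclass(frozen=True)
class MouseUnit:
    """One mouse training unit: accession + arm + strain selection."""
    disease: str
    accession: str
    induction: str
    arm: str
    strains: tuple[str, ...]

    @property
    def label(self) -> str:
        strain = "+".join(self.strains)
        return f"{self.accession}[{self.induction}:{self.arm}|{strain}]"


@dataclass(frozen=True)
class HumanUnit:
    """One human test unit: accession + platform."""
    disease: str
    accession: str
    platform: str

    @property
    def label(self) -> str:
        return f"{self.accession}[{self.platform}]"


@dataclass(frozen=True)
class CaseStudyDescriptor:
    index: int
    disease: str
    mouse: MouseUnit
    human: HumanUnit

    @property
    def identifier(self) -> str:
        return f"{self.index:02d}:{self.disease}:{self.mouse.label}->{self.human.label}"


def mouse_units(cohorts: tuple[MouseCohort, ...] = MOUSE_COHORTS) -> list[MouseUnit]:
    """Partition mouse cohorts into training units (arm x strain, + combined)."""
    units: list[MouseUnit] = []
    for c in cohorts:
        for arm in c.arms:
            for strain in c.strains:
                units.append(MouseUnit(c.disease, c.accession, c.induction,
                                       arm, (strain,)))
            if len(c.strains) > 1:
                units.append(MouseUnit(c.disease, c.accession, c.induction,
                                       arm, tuple(c.strains)))
    return units


def human_units(cohorts: tuple[HumanCohort, ...] = HUMAN_COHORTS) -> list[HumanUnit]:
    """Partition human cohorts into test units (one per platform)."""
    return [HumanUnit(c.disease, c.accession, p)
            for c in cohorts for p in c.platforms]


def enumerate_case_studies(
        mouse_cohorts: tuple[MouseCohort, ...] = MOUSE_COHORTS,
        human_cohorts: tuple[HumanCohort, ...] = HUMAN_COHORTS,
) -> list[CaseStudyDescriptor]:
    """All (mouse unit, human unit) pairs sharing a disease, in stable order."""
    out: list[CaseStudyDescriptor] = []
    idx = 1
    for mu in mouse_units(mouse_cohorts):
        for hu in human_units(human_cohorts):
            if mu.disease == hu.disease:
                out.append(CaseStudyDescriptor(idx, mu.disease, mu, hu))
                idx += 1
    return out
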