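"""Published normative summary statistics used as recomputation inputs.

Reference values from a normative ultrasound study of suprapatellar femoral
cartilage thickness in 232 healthy adults (132 female, 100 male; four age
bands from young adulthood to retirement age), measured bilaterally at the
lateral condyle, intercondylar area and medial condyle with triplicate
readings per site.  Only per-group sample moments (n, mean, SD in mm) and
categorical counts were published; subject-level data were not deposited,
so these summaries are the inputs from which group statistics are
recomputed and against which the synthetic cohort generator is calibrated.
"""

from __future__ import annotations

from .compare import GroupSummary

SITES = (
    "right_lateral", "right_middle", "right_medial",
    "left_lateral", "left_middle", "left_medial",
)

AGE_GROUPS = ("young", "middle", "older", "retirement")
#: numeric labels conventional in the published tables (1 = youngest)
AGE_GROUP_NUMBERS = {g: str(i + 1) for i, g in enumerate(AGE_GROUPS)}

#: per-site thickness (n, mean mm, SD mm) for the whole sample and by sex
THICKNESS_BY_SEX: dict[str, dict[str, tuple[int, float, float]]] = {
    "right_lateral": {"all": (232, 3.380, 0.385),
                      "female": (132, 3.288, 0.406),
                      "male": (100, 3.502, 0.320)},
    "right_middle": {"all": (232, 2.880, 0.252),
                     "female": (132, 2.856, 0.243),
                     "male": (100, 2.911, 0.262)},
    "right_medial": {"all": (232, 3.320, 0.407),
                     "female": (132, 3.210, 0.381),
                     "male": (100, 3.468, 0.395)},
    "left_lateral": {"all": (232, 3.364, 0.387),
                     "female": (132, 3.225, 0.353),
                     "male": (100, 3.548, 0.354)},
    "left_middle": {"all": (232, 2.902, 0.294),
                    "female": (132, 2.839, 0.284),
                    "male": (100, 2.984, 0.288)},
    "left_medial": {"all": (232, 3.305, 0.409),
                    "female": (132, 3.172, 0.362),
                    "male": (100, 3.479, 0.404)},
}

#: per-site thickness by age group, whole sample (ns 56/70/47/59)
THICKNESS_BY_AGE_ALL: dict[str, dict[str, tuple[int, float, float]]] = {
    "right_lateral": {"young": (56, 3.468, 0.420), "middle": (70, 3.271, 0.338),
                      "older": (47, 3.312, 0.374), "retirement": (59, 3.481, 0.376)},
    "right_middle": {"young": (56, 2.855, 0.258), "middle": (70, 2.909, 0.266),
                     "older": (47, 2.878, 0.240), "retirement": (59, 2.869, 0.243)},
    "right_medial": {"young": (56, 3.266, 0.391), "middle": (70, 3.273, 0.359),
                     "older": (47, 3.275, 0.404), "retirement": (59, 3.464, 0.450)},
    "left_lateral": {"young": (56, 3.434, 0.408), "middle": (70, 3.269, 0.391),
                     "older": (47, 3.331, 0.323), "retirement": (59, 3.439, 0.391)},
    "left_middle": {"young": (56, 2.881, 0.329), "middle": (70, 2.952, 0.269),
                    "older": (47, 2.911, 0.270), "retirement": (59, 2.854, 0.305)},
    "left_medial": {"young": (56, 3.248, 0.461), "middle": (70, 3.324, 0.351),
                    "older": (47, 3.179, 0.330), "retirement": (59, 3.436, 0.446)},
}

#: females only (ns 33/43/25/31)
THICKNESS_BY_AGE_FEMALE: dict[str, dict[str, tuple[int, float, float]]] = {
    "right_lateral": {"young": (33, 3.387, 0.444), "middle": (43, 3.182, 0.337),
                      "older": (25, 3.249, 0.435), "retirement": (31, 3.361, 0.406)},
    "right_middle": {"young": (33, 2.856, 0.246), "middle": (43, 2.870, 0.262),
                     "older": (25, 2.835, 0.209), "retirement": (31, 2.853, 0.249)},
    "right_medial": {"young": (33, 3.201, 0.375), "middle": (43, 3.212, 0.389),
                     "older": (25, 3.142, 0.327), "retirement": (31, 3.271, 0.422)},
    "left_lateral": {"young": (33, 3.305, 0.358), "middle": (43, 3.162, 0.371),
                     "older": (25, 3.208, 0.315), "retirement": (31, 3.242, 0.348)},
    "left_middle": {"young": (33, 2.826, 0.306), "middle": (43, 2.899, 0.251),
                    "older": (25, 2.878, 0.270), "retirement": (31, 2.739, 0.299)},
    "left_medial": {"young": (33, 3.098, 0.425), "middle": (43, 3.201, 0.304),
                    "older": (25, 3.125, 0.320), "retirement": (31, 3.250, 0.392)},
}

#: males only (ns 23/27/22/28)
THICKNESS_BY_AGE_MALE: dict[str, dict[str, tuple[int, float, float]]] = {
    "right_lateral": {"young": (23, 3.584, 0.361), "middle": (27, 3.412, 0.293),
                      "older": (22, 3.384, 0.283), "retirement": (28, 3.614, 0.293)},
    "right_middle": {"young": (23, 2.855, 0.281), "middle": (27, 2.972, 0.264),
                     "older": (22, 2.927, 0.267), "retirement": (28, 2.887, 0.238)},
    "right_medial": {"young": (23, 3.361, 0.403), "middle": (27, 3.370, 0.285),
                     "older": (22, 3.427, 0.437), "retirement": (28, 3.678, 0.383)},
    "left_lateral": {"young": (23, 3.619, 0.411), "middle": (27, 3.439, 0.367),
                     "older": (22, 3.471, 0.277), "retirement": (28, 3.656, 0.316)},
    "left_middle": {"young": (23, 2.960, 0.351), "middle": (27, 3.037, 0.279),
                    "older": (22, 2.950, 0.271), "retirement": (28, 2.981, 0.261)},
    "left_medial": {"young": (23, 3.464, 0.432), "middle": (27, 3.518, 0.339),
                    "older": (22, 3.241, 0.338), "retirement": (28, 3.642, 0.415)},
}

#: age-band counts (rows: young..retirement) by sex (columns: female, male)
AGE_SEX_COUNTS = [[33, 23], [43, 27], [25, 22], [31, 28]]

#: reported intra-rater reliability bands across sites and sexes
ICC_BAND = (0.91, 0.99)
SEM_PCT_BAND = (1.3, 2.3)
CV_PCT_BAND = (1.25, 2.27)


def age_summary(
    table: dict[str, dict[str, tuple[int, float, float]]],
    site: str,
    numeric_labels: bool = True,
) -> GroupSummary:
    """GroupSummary for one site's four age groups from a normative table."""
    row = table[site]
    labels = [AGE_GROUP_NUMBERS[g] if numeric_labels else g
              for g in AGE_GROUPS]
    return GroupSummary(
        labels=labels,
        ns=[row[g][0] for g in AGE_GROUPS],
        means=[row[g][1] for g in AGE_GROUPS],
        sds=[row[g][2] for g in AGE_GROUPS],
        site=site,
    )


def sex_summary(site: str) -> GroupSummary:
    """Female-vs-male GroupSummary for one site."""
    row = THICKNESS_BY_SEX[site]
    return GroupSummary(
        labels=["female", "male"],
        ns=[row["female"][0], row["male"][0]],
        means=[row["female"][1], row["male"][1]],
        sds=[row["female"][2], row["male"][2]],
        site=site,
    )


def site_means(column: str = "all") -> dict[str, float]:
    """Per-site mean thickness for 'all', 'female' or 'male'."""
    return {s: THICKNESS_BY_SEX[s][column][1] for s in SITES}


def cohort_spec_from_normative(
    seed: int = 0,
    sem_pct: float = 1.8,
    between_subject_sd: float = 0.30,
    table_female=None,
    table_male=None,
):
    """Cohort spec calibrated to the normative tables.

    Group means come from the by-sex-by-age tables; the reading-error SD is
    set from the target SEM% at the pooled grand mean, and the
    between-subject SD defaults to a value typical of the published
    per-group SDs.
    """
    from .synth import CohortSpec, within_sd_from_sem_pct

    table_female = table_female or THICKNESS_BY_AGE_FEMALE
    table_male = table_male or THICKNESS_BY_AGE_MALE
    group_means = {}
    n_per_group = {}
    for sex, table in (("female", table_female), ("male", table_male)):
        for g in AGE_GROUPS:
            group_means[(sex, g)] = {s: table[s][g][1] for s in SITES}
            n_per_group[(sex, g)] = table[SITES[0]][g][0]
    grand = sum(site_means("all").values()) / len(SITES)
    return CohortSpec(
        group_means=group_means,
        n_per_group=n_per_group,
        between_subject_sd=between_subject_sd,
        within_subject_sd=within_sd_from_sem_pct(sem_pct, grand),
        n_readings=3,
        seed=seed,
    )
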