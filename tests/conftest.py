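import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from immunoscore import (
    SyntheticCohortSpec,
    build_reference_table,
    bundled_paper_table,
    generate_healthy_cohort,
)

# Independently typed copy of the published per-age-group summary cells,
# "mean±sd (lower-upper)", used to cross-check the bundled fixture
# transcription.  Groups in order: children, adolescents, adults, elders.
PUBLISHED_CELLS = {
    "cd4_count": ["1260±399 (635-1979)", "927±287 (560-1653)", "648±203 (360-1074)", "652±187 (367-1007)"],
    "cd8_count": ["880±343 (426-1553)", "728±262 (397-1382)", "424±171 (180-847)", "355±154 (116-681)"],
    "b_count": ["695±251 (251-1240)", "457±173 (218-905)", "184±81 (53-352)", "216±140 (67-537)"],
    "nk_count": ["381±243 (89-905)", "345±228 (86-934)", "364±165 (154-732)", "473±239 (125-1000)"],
    "cd4_func_pct": ["10.23±4.16 (4.08-17.17)", "12.28±4.86 (5.43-20.35)", "23.72±8.12 (12.34-40.53)", "22.26±7.52 (8.83-34.43)"],
    "cd8_func_pct": ["26.89±10.77 (8.95-46.18)", "29.13±10.83 (13.63-56.57)", "56.08±17.92 (22.76-87.38)", "70.46±14.33 (42.84-92.36)"],
    "nk_func_pct": ["67.28±14.57 (40.76-85.99)", "67.77±13.16 (39.70-87.66)", "77.29±9.95 (57.73-91.48)", "76.37±9.52 (59.79-90.61)"],
    "cd28_cd4_pct": ["98.17±4.03 (89.50-99.98)", "97.92±2.72 (88.95-99.95)", "92.81±7.6 (71.81-99.88)", "91.61±9.10 (66.26-99.83)"],
    "hladr_cd4_pct": ["9.68±4.79 (5.29-24.40)", "10.64±4.15 (5.11-19.71)", "16.23±7.02 (5.97-34.34)", "20.35±8.25 (9.07-40.22)"],
    "cd45ro_cd4_pct": ["28.77±7.71 (13.63-43.39)", "40.37±9.88 (22.48-58.08)", "61.09±14 (36.21-88.06)", "67.82±14.07 (37.46-93.85)"],
    "cd28_cd8_pct": ["71.58±12.49 (52.47-91.71)", "71.39±12.36 (45.28-88.65)", "58±15.87 (26.72-84.13)", "47.57±16.5 (20.60-82.40)"],
    "hladr_cd8_pct": ["23.26±11.82 (7.42-47.14)", "25.13±10.45 (9.98-46.31)", "39.09±15.71 (14.96-72.95)", "51.83±13.98 (22.97-74.98)"],
    "cd4_num_x_func": ["125±58 (57-225)", "108±40 (57-209)", "153±75 (61-328)", "147±73 (44-311)"],
    "cd8_num_x_func": ["240±143 (65-565)", "212±126 (86-489)", "242±143 (79-564)", "259±74 (67-553)"],
    "nk_num_x_func": ["254±157 (37-585)", "241±184 (44-780)", "286±142 (90-674)", "216±125 (80-832)"],
    "cd28_cd4_num": ["1236±392 (631-1925)", "909±288 (536-1638)", "600±190 (318-1001)", "594±173 (320-894)"],
    "hladr_cd4_num": ["121±70 (43-299)", "95±37 (44-176)", "103±52 (35-232)", "135±78 (47-339)"],
    "cd45ro_cd4_num": ["347±109 (220-557)", "358±94 (225-570)", "393±153 (165-735)", "444±168 (219-748)"],
    "cd28_cd8_num": ["618±233 (243-1011)", "508±174 (262-950)", "236±98 (104-435)", "134±50 (57-286)"],
    "hladr_cd8_num": ["221±183 (38-565)", "185±113 (67-452)", "169±110 (39-478)", "132±48 (46-436)"],
}

GROUP_ORDER = ("children", "adolescents", "adults", "elders")


def parse_cell(cell: str) -> tuple[float, float, float, float]:
    """'mean±sd (lower-upper)' -> (mean, sd, lower, upper)."""
    stats, limits = cell.split(" (")
    mean, sd = stats.split("±")
    lower, upper = limits.rstrip(")").split("-")
    return float(mean), float(sd), float(lower), float(upper)


@pytest.fixture(scope="session")
def paper_table():
    return bundled_paper_table()


@pytest.fixture(scope="session")
def big_cohort():
    """10,000 subjects per age group from the default generator."""
    spec = SyntheticCohortSpec(
        group_sizes={g: 10_000 for g in GROUP_ORDER}, seed=101
    )
    return generate_healthy_cohort(spec)


@pytest.fixture(scope="session")
def big_table(big_cohort):
    return build_reference_table(big_cohort, provenance="generator_n10000")


@pytest.fixture(scope="session")
def heldout_cohort():
    """Fresh 2,500/group draw from the same distribution as big_cohort."""
    spec = SyntheticCohortSpec(
        group_sizes={g: 2_500 for g in GROUP_ORDER}, seed=202
    )
    return generate_healthy_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(4242)
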