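import pytest

from dupggaa import MotifPattern, load_emsa_probes
from dupggaa.io import revcomp

# Presence calls for the six bundled EMSA duplex probes, in file order:
# only the intact duplicated-motif probes are positive.
PROBE_PRESENCE = {
    "OAS1_-340_-301": True,
    "OAS1_-379_-331": False,
    "OAS1_-330_-301": True,
    "mtTTCC1": False,
    "mtTTCC2": False,
    "dupGGAA_competitor": True,
}


def naive_scan(seq: str, pattern: MotifPattern) -> set:
    """Brute-force double-loop scanner: tests every (start, spacer, pair type)
    directly with substring comparison.  Independent oracle for scan_sequence."""
    words = {"F": pattern.core, "R": revcomp(pattern.core)}
    if words["F"] == words["R"]:
        pts = {"FF"}
    elif pattern.both_strands:
        pts = set(pattern.pair_types)
    else:
        pts = set(pattern.pair_types) & {"FF", "FR", "RF"}
    out = set()
    for pt in pts:
        w1, w2 = words[pt[0]], words[pt[1]]
        for i in range(len(seq)):
            for s in range(pattern.spacer_min, pattern.spacer_max + 1):
                j = i + 4 + s
                if seq[i : i + 4] == w1 and len(seq[j : j + 4]) == 4 and seq[j : j + 4] == w2:
                    out.add((i, j + 4, s, pt))
    return out


@pytest.fixture(scope="session")
def probes():
    return load_emsa_probes()


@pytest.fixture
def default_pattern():
    return MotifPattern()
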