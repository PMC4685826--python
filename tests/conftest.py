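import numpy as np
import pytest

from marfungi.iolib import Read, Sample, SampleTable

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate_subs(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply exactly k substitutions at distinct positions."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=k, replace=False):
        chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
    return "".join(chars)


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def semiglobal_identity_oracle(a: str, b: str) -> tuple[float, float]:
    """Pure-DP oracle for the pipeline's pairwise identity: match +1,
    mismatch -1, internal gap -2, terminal gap -1/base. Returns
    (percent identity excluding terminal-gap columns, optimal score)."""
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        score[i][0] = -float(i)  # leading end gaps at -1/base
    for j in range(m + 1):
        score[0][j] = -float(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i][j] = max(
                score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1),
                score[i - 1][j] - 2,
                score[i][j - 1] - 2,
            )
    # trailing end gaps at -1/base: best over the last row/column
    best, bi, bj = float("-inf"), n, m
    for i in range(n + 1):
        v = score[i][m] - (n - i)
        if v > best:
            best, bi, bj = v, i, m
    for j in range(m + 1):
        v = score[n][j] - (m - j)
        if v > best:
            best, bi, bj = v, n, j
    # traceback of the internal region from (bi, bj)
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0:
        diag = score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else -1)
        if score[i][j] == diag:
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] - 2:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    identity = 100.0 * matches / columns if columns else 0.0
    return identity, best


def make_sample_table(n_rna: int = 2, n_dna: int = 2) -> SampleTable:
    samples = []
    for i in range(n_rna):
        samples.append(Sample(f"R{i+1}", f"Site{i+1}", "water_column",
                              "surface", "0.8-20um", "RNA"))
    for i in range(n_dna):
        samples.append(Sample(f"D{i+1}", f"Site{i+1}", "water_column",
                              "surface", "0.8-20um", "DNA"))
    return SampleTable(samples)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noiseless synthetic dataset shared across tests."""
    from marfungi import synthdata
    cfg = synthdata.SynthConfig(
        n_sites=3, n_resident_taxa=6, n_transient_taxa=20,
        n_background_taxa=4, reads_per_sample=40, read_length=120,
        epsilon=0.0, seed=7)
    refdb = synthdata.generate_reference_db(cfg)
    reads, samples, truth = synthdata.simulate_dataset(refdb, cfg)
    return cfg, refdb, reads, samples, truth
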