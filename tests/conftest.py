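import numpy as np
import pytest

from radsym import BCGI, build_marker_db, generate_genomes


@pytest.fixture(scope="session")
def planted():
    """Three synthetic genomes with 8 planted BcgI sites each, plus the
    ground-truth tag registry."""
    genomes, registry = generate_genomes(
        n_species=3, genome_len=3000, sites_per_genome=8, enzyme=BCGI, seed=11
    )
    return genomes, registry


@pytest.fixture(scope="session")
def db(planted):
    genomes, _ = planted
    return build_marker_db(genomes, BCGI)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def anova_f_oracle(samples):
    """One-way ANOVA F from explicit sums of squares."""
    all_v = np.concatenate(samples)
    grand = all_v.mean()
    k, N = len(samples), len(all_v)
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    return (ssb / (k - 1)) / (ssw / (N - k))


def kw_h_oracle(samples):
    """Tie-corrected Kruskal-Wallis H from explicit mean ranks."""
    from scipy.stats import rankdata

    all_v = np.concatenate(samples)
    N = len(all_v)
    ranks = rankdata(all_v)
    start, H = 0, 0.0
    for s in samples:
        r = ranks[start:start + len(s)]
        start += len(s)
        H += len(s) * (r.mean() - (N + 1) / 2) ** 2
    H *= 12 / (N * (N + 1))
    _, counts = np.unique(all_v, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (N**3 - N)
    return H / tie


def pearson_oracle(x, y):
    """Pearson r and two-sided p via the exact t transform."""
    from scipy.stats import t as tdist

    r = np.corrcoef(x, y)[0, 1]
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, 2 * tdist.sf(abs(t), n - 2)


def naive_scan(sequence: str, enzyme):
    """Independent digestion oracle: position-by-position IUPAC matching
    on both strands, no regex."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    }

    def rc(s):
        return "".join(comp[c] for c in reversed(s))

    def matches(window, pattern):
        return all(c in iupac[p] for c, p in zip(window, pattern))

    seq = sequence.upper()
    rlen = len(enzyme.recognition)
    flank = enzyme.flank_len
    hits = []
    for strand in "+-":
        pattern = enzyme.recognition if strand == "+" else rc(enzyme.recognition)
        # pattern as seen on forward coords for '-' strand sites
        for s in range(len(seq) - rlen + 1):
            if not matches(seq[s:s + rlen], pattern):
                continue
            start, end = s - flank, s + rlen + flank
            if start < 0 or end > len(seq):
                continue
            window = seq[start:end]
            if "N" in window:
                continue
            tag = window if strand == "+" else rc(window)
            hits.append((start, strand, tag))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
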