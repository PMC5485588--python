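import numpy as np
import pandas as pd
import pytest

from grape import BatchSpec, GeneratorConfig, generate_cohort, generate_gmt


@pytest.fixture
def small_expr():
    """4 genes x 3 samples with a known ordering per sample."""
    return pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 4.0],
            "s2": [4.0, 3.0, 2.0, 1.0],
            "s3": [2.0, 1.0, 4.0, 3.0],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene"),
    )


@pytest.fixture
def two_class_cohort():
    """Two classes with reversed consensus orderings, mild noise."""
    cfg = GeneratorConfig(
        seed=42,
        n_genes=30,
        n_per_class=20,
        class_orders={"alpha": list(range(30)), "beta": list(range(29, -1, -1))},
        flip_noise=0.1,
    )
    return generate_cohort(cfg)


@pytest.fixture
def pathway_sets(two_class_cohort):
    expr, _ = two_class_cohort
    return generate_gmt(3, (8, 12), list(expr.index), np.random.default_rng(7))


def random_template_instance(rng, m=None, n_samples=None):
    """A random (template, sample bits) pair for distance tests."""
    from grape import PairIndex, binarize_matrix, build_template

    m = int(m if m is not None else rng.integers(3, 31))
    n_samples = int(n_samples if n_samples is not None else rng.integers(2, 9))
    pi = PairIndex([f"g{k}" for k in range(m)])
    values = rng.normal(size=(m, n_samples))
    bits = binarize_matrix(values, pi, rng)
    template = build_template(bits, pi, rng)
    sample = binarize_matrix(rng.normal(size=(m, 1)), pi, rng)[0]
    return template, sample


def brute_force_weighted_distance(template, bits, weight_fn):
    """Independent pair-loop oracle for the weighted reversal distance.

    Loops over explicit pair tuples with no vectorisation; shares nothing
    with the implementation under test beyond the template contents.
    """
    genes = list(template.pair_index.genes)
    total = 0.0
    normalizer = 0.0
    k = 0
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            w = weight_fn(float(template.probability[k]))
            normalizer += w
            if int(template.binary[k]) != int(bits[k]):
                total += w
            k += 1
    if normalizer == 0:
        return 0.0
    return total / normalizer
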