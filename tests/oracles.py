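"""Independent reference implementations used only to cross-check the package.

These are deliberately written as direct, clause-by-clause / formula-by-formula
transcriptions, sharing no code with the implementation they audit.
"""

import math

from scipy.stats import t as t_dist


def brute_force_filter(call, thresholds, missing_policy):
    """Re-evaluate the eight hard-filter clauses one by one.

    Returns (passed, failed, missing) with clause names, computed without any
    of the package's filtering code paths."""
    failed, missing = [], []

    def check(name, value, fails_when):
        if value is None:
            missing.append(name)
            if missing_policy == "strict":
                failed.append(name)
        elif fails_when(value):
            failed.append(name)

    ann = call.annotations
    check("DP", ann.get("DP"), lambda v: v <= thresholds.min_dp)
    check("QUAL", call.qual, lambda v: v <= thresholds.min_qual)
    check("QD", ann.get("QD"), lambda v: v < thresholds.fail_qd_below)
    check("FS", ann.get("FS"), lambda v: v > thresholds.fail_fs_above)
    check("MQ", ann.get("MQ"), lambda v: v < thresholds.fail_mq_below)
    check(
        "HaplotypeScore",
        ann.get("HaplotypeScore"),
        lambda v: v > thresholds.fail_haplotypescore_above,
    )
    check("MQRankSum", ann.get("MQRankSum"), lambda v: v < thresholds.fail_mqranksum_below)
    check(
        "ReadPosRankSum",
        ann.get("ReadPosRankSum"),
        lambda v: v < thresholds.fail_readposranksum_below,
    )
    return (not failed, sorted(failed), sorted(missing))


def welch_t_p_value(xs, ys):
    """Two-sided Welch t-test from the closed-form t statistic and
    Welch-Satterthwaite degrees of freedom."""
    n1, n2 = len(xs), len(ys)
    m1 = sum(xs) / n1
    m2 = sum(ys) / n2
    v1 = sum((x - m1) ** 2 for x in xs) / (n1 - 1)
    v2 = sum((y - m2) ** 2 for y in ys) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t_stat = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * t_dist.sf(abs(t_stat), df)


def random_filter_call(rng, make_call):
    """A random call mixing wide-range, boundary and missing annotation values."""
    boundary = {
        "DP": 20,
        "QUAL": 30.0,
        "QD": 2.0,
        "FS": 60.0,
        "MQ": 35.0,
        "HaplotypeScore": 13.0,
        "MQRankSum": -12.5,
        "ReadPosRankSum": -8.0,
    }
    wide = {
        "DP": lambda: int(rng.integers(0, 200)),
        "QUAL": lambda: float(rng.uniform(0, 500)),
        "QD": lambda: float(rng.uniform(0, 40)),
        "FS": lambda: float(rng.uniform(0, 150)),
        "MQ": lambda: float(rng.uniform(0, 80)),
        "HaplotypeScore": lambda: float(rng.uniform(0, 30)),
        "MQRankSum": lambda: float(rng.uniform(-20, 20)),
        "ReadPosRankSum": lambda: float(rng.uniform(-20, 20)),
    }
    overrides = {}
    qual = 100.0
    for name in boundary:
        u = rng.random()
        if u < 0.2:
            value = boundary[name]
        elif u < 0.4 and name != "QUAL":
            value = None  # missing annotation
        else:
            value = wide[name]()
        if name == "QUAL":
            qual = value if value is not None else 100.0
        else:
            overrides[name] = value
    return make_call(pos=int(rng.integers(1, 10**8)), qual=qual, **overrides)
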