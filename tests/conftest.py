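import numpy as np
import pytest

from dualrec.design import PRESETS, build_design
from dualrec.model import build_dual_recollection_model, default_sharing_scheme

ALL_PRESETS = sorted(PRESETS)


@pytest.fixture(scope="session")
def exp3_high():
    return build_design("exp3-high")


@pytest.fixture(scope="session")
def exp3_model(exp3_high):
    return build_dual_recollection_model(exp3_high)


def tree_type(design, probe, item_class):
    """Classify a (probe, item class) category for the enumeration oracle."""
    if item_class in design.distractor_classes:
        return "distractor"
    asked = design.probe_targets.get(probe)
    if asked is None:
        return "either"
    feature_values = design.class_features(item_class).values()
    return "congruent" if asked in feature_values else "incongruent"


def oracle_p_yes(kind, rc, rt, f, b):
    """Brute-force P(yes): enumerate the joint success/failure outcomes of
    the four latent processes and apply the dual-recollection decision rules
    directly, independent of any tree representation."""
    total = 0.0
    for s_rc in (0, 1):
        for s_rt in (0, 1):
            for s_f in (0, 1):
                for s_b in (0, 1):
                    prob = (
                        (rc if s_rc else 1 - rc)
                        * (rt if s_rt else 1 - rt)
                        * (f if s_f else 1 - f)
                        * (b if s_b else 1 - b)
                    )
                    if kind == "congruent":
                        yes = s_rc or s_rt or s_b
                    elif kind == "incongruent":
                        yes = (not s_rc) and (s_rt or s_b)
                    elif kind == "either":
                        yes = s_rc or s_rt or s_f or s_b
                    elif kind == "distractor":
                        yes = s_b
                    else:
                        raise ValueError(kind)
                    total += prob * yes
    return total


def oracle_category_probabilities(design, model, theta):
    """Oracle P(yes) per category for a full preset model."""
    scheme = default_sharing_scheme(design)
    out = {}
    for probe, item_class in model.categories:
        kind = tree_type(design, probe, item_class)
        b = theta[scheme[(probe, item_class)]]
        if kind == "distractor":
            rc = rt = f = 0.0
        else:
            rc = theta[f"RC_{item_class}"]
            rt = theta[f"RT_{item_class}"]
            f = theta.get(f"F_{item_class}", 0.0)
        out[(probe, item_class)] = oracle_p_yes(kind, rc, rt, f, b)
    return out


def random_theta(model, rng):
    return {p: float(v) for p, v in zip(model.parameter_names, rng.uniform(size=model.n_parameters))}
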