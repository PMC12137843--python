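import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def classifier_run():
    """Train the stiffness classifier on well-separated phantoms for a
    given seed; cached per seed for the whole session.

    Returns a factory: seed -> dict with the trained model, the held-out
    test tensors/labels, and the training record.
    """
    from cellstiff.models import ClassifierSpec, build_classifier, train_model
    from cellstiff.preprocessing import images_to_tensor, split_dataset
    from cellstiff.synthetic import generate_phantom_dataset

    cache: dict[int, dict] = {}

    def get(seed: int) -> dict:
        if seed in cache:
            return cache[seed]
        images = generate_phantom_dataset(1000, 1000, seed=seed)
        x = images_to_tensor(images)
        y = np.array([1 if im.label == "stiff" else 0 for im in images])
        split = split_dataset(list(range(len(images))), labels=y, seed=seed)
        tr, va, te = (np.array(s, dtype=int) for s in split)
        model = build_classifier(ClassifierSpec(seed=seed))
        model, record = train_model(model, x[tr], y[tr], x[va], y[va],
                                    epochs=6, seed=seed)
        cache[seed] = {"model": model, "x_test": x[te], "y_test": y[te],
                       "record": record}
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def wt_spectrum():
    """500 unlabeled phantoms spanning the full stiffness range, with
    their ground-truth moduli — the synthetic stand-in for untreated,
    intermediate-stiffness cells."""
    from cellstiff.preprocessing import images_to_tensor
    from cellstiff.synthetic import generate_phantom_spectrum

    images = generate_phantom_spectrum(500, seed=202)
    x = images_to_tensor(images)
    e = np.array([im.modulus_pa for im in images])
    return x, e
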