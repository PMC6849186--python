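import numpy as np
import pytest

from screenflow.chunked import ChunkedTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def make_table(x, names=None, chunk_rows=50):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if names is None:
        names = [f"c{j}" for j in range(x.shape[1])]
    return ChunkedTable.from_array(x, names, chunk_rows)


def write_example_config(path, input_path, feature_file, outfolder,
                         seed=7, extra=""):
    """The worked-example pipeline: pca+ica to 5 dims, gmm+kmeans with
    50/100 centers on each reduction, glm+forest on the infection label."""
    path.write_text(
        f"input: {input_path}\n"
        f"features: {feature_file}\n"
        "response: is_infected\n"
        "family: binomial\n"
        "dimension_reduction: pca, ica\n"
        "n_components: 5\n"
        "clustering: gmm, kmeans\n"
        "n_centers: 50, 100\n"
        "regression: glm, forest\n"
        f"outfolder: {outfolder}\n"
        f"seed: {seed}\n"
        "sparkparams: '--driver-memory=15G'\n"
        + extra
    )
    return path
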