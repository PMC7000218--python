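import numpy as np
import pytest

from zincycle import SyntheticConfig, render_movie, segment_nuclei
from zincycle.traces import CellTrace, TraceEnsemble


@pytest.fixture(scope="session")
def movie_config():
    return SyntheticConfig(seed=5, duration=24.0, image_size=(224, 224),
                           image_noise_sd=2.0)


@pytest.fixture(scope="session")
def division_movie(movie_config):
    """Four-cell movie, two planted divisions (at 10 h and 14 h)."""
    t = movie_config.time_grid
    traces = []
    for i in range(4):
        divs = [10.0 + 4.0 * i] if i < 2 else []
        traces.append(
            CellTrace(cell_id=i, t=t, ratio=np.full(t.size, 1.2),
                      division_times=divs)
        )
    ensemble = TraceEnsemble(traces)
    return ensemble, render_movie(ensemble, movie_config)


@pytest.fixture(scope="session")
def division_movie_masks(division_movie):
    _, movie = division_movie
    return [segment_nuclei(frame, frame=f) for f, frame in enumerate(movie.h2b)]
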