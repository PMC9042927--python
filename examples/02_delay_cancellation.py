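"""Hemodynamic-delay cancellation from a time-reversed session pair.

The raw response phase of a pixel mixes its stimulus preference with the
hemodynamic delay.  Running the same tone sequence upward and downward and
combining the two phase maps separates the two quantities per pixel.
"""

import numpy as np

from wfmap import (SessionConfig, combine_reversed_sessions,
                   extract_channel_response, pixel_spectrum, select_candidates,
                   summarize_delay, synthesize_movie, tonotopy_sequence)
from wfmap.synthetic import random_truth, time_reversed_truth

config = SessionConfig(530.0, 5.0, 400.0,
                       [tonotopy_sequence("up").to_channel()])
ch = config.channels[0]

truth = random_truth((30, 30), ["tones"], [20.0], seed=5,
                     amplitude_permille=1.0, delay_range_s=(3.0, 4.5))
rev_truth = time_reversed_truth(truth, {"tones": 20.0})

fwd = extract_channel_response(pixel_spectrum(
    synthesize_movie(truth, config, noise_sd_permille=0.3, seed=1)), ch, -1)
rev = extract_channel_response(pixel_spectrum(
    synthesize_movie(rev_truth, config, noise_sd_permille=0.3, seed=2)), ch, -1)

tmap = combine_reversed_sessions(fwd, rev)
candidates = select_candidates(tmap, fraction=0.10)
summary = summarize_delay(tmap.delay_s, candidates, accept_range=(2.0, 5.7))

print(f"planted delays 3.0-4.5 s; recovered mean over the top-decile "
      f"candidates: {summary.mean_s:.2f} s ({summary.n_in_range} pixels)")
err = np.abs(tmap.delay_s - truth.delay_s)[candidates]
print(f"median per-pixel delay error {np.median(err):.3f} s")
# In vivo this mean is the per-subject hemodynamic delay; group averages of
# 3.9 s (tones) / 3.5 s (visual sweeps) feed the fixed single-session
# compensation in wfmap.phase_mapping.
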