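"""Independent reference implementations used to validate the package.

These are deliberately written as plain Python loops over dicts, separate
from the vectorized implementations they check.
"""

import numpy as np


def oracle_events(tracks, dots, cfg, smoothed):
    """Exhaustive frame-by-frame encounter detection and scoring."""
    out = []
    R = cfg.encounter_radius
    W = cfg.response_window_frames
    nf = tracks.n_frames
    for a in range(tracks.n_animals):
        for j in range(dots.n_dots):
            dist = [float(np.hypot(*(tracks.positions[a, t] - dots.positions[j, t])))
                    for t in range(nf)]
            t = 1
            while t < nf:
                if dist[t] <= R and dist[t - 1] > R:
                    onset = t
                    out_run = 0
                    close = None
                    u = t + 1
                    while u < nf:
                        out_run = out_run + 1 if dist[u] > R else 0
                        if out_run >= 3 and u >= onset + W:
                            close = u
                            break
                        u += 1
                    close = nf - 1 if close is None else close
                    ev = {"animal": a, "dot": int(dots.dot_ids[j]),
                          "onset": onset, "offset": close,
                          "min_d": min(dist[onset:close + 1])}
                    if onset + W > nf - 1:
                        ev["censored"] = True
                        ev["success"] = False
                    else:
                        base = smoothed[a][onset]
                        deltas = [abs(smoothed[a][u2] - base)
                                  for u2 in range(onset + 1, onset + W + 1)]
                        ev["censored"] = False
                        ev["success"] = max(deltas) >= cfg.avoidance_delta_v
                    out.append(ev)
                    t = close + 1
                else:
                    t += 1
    out.sort(key=lambda e: (e["onset"], e["animal"], e["dot"]))
    return out
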