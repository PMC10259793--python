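"""Shared constructors for hand-built cell geometry used across test modules."""

import numpy as np

from hyphamorph.cells import CellRecord
from hyphamorph.geometry import PolylineTrace


def make_hypha_cell(junction_deg=0.0, kink_degs=(), seg_len=1.0,
                    cell_id="c0", has_bud=True, body_len=2.0):
    """Build a budding cell whose hypha realizes the given turn angles.

    The body axis runs along +x; the hypha emerges at the +x pole turned by
    ``junction_deg`` and then turns by each kink angle in alternating
    directions. Turn magnitudes are exact by construction.
    """
    body = PolylineTrace(np.array([[0.0, 0.0], [body_len, 0.0]]),
                         role="body_axis")
    ang = np.radians(junction_deg)
    d = np.array([np.cos(ang), np.sin(ang)])
    pts = [np.array([body_len, 0.0])]
    sign = -1.0
    for k in list(kink_degs) + [None]:
        pts.append(pts[-1] + d * seg_len)
        if k is None:
            break
        rot = np.radians(sign * k)
        c, s = np.cos(rot), np.sin(rot)
        d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        sign = -sign
    hypha = PolylineTrace(np.asarray(pts), role="hypha")
    stage = "budding" if has_bud else "hypha_no_bud"
    bud = None
    if has_bud:
        bud = PolylineTrace(np.vstack([pts[-1], pts[-1] + d * 0.9]),
                            role="bud_path")
    return CellRecord(cell_id=cell_id, body_axis=body, hyphae=(hypha,),
                      bud_path=bud, has_bud=has_bud, stage=stage)


def make_profile_cell(cell_id, length_um, peak_arc_um, channel="g",
                      hypha_start_um=1.0, step=0.05, width_sigma=0.0):
    """A straight budding cell with an analytic profile peaked at a given arc."""
    body = PolylineTrace(np.array([[0.0, 0.0], [hypha_start_um, 0.0]]),
                         role="body_axis")
    hypha = PolylineTrace(np.array([[hypha_start_um, 0.0], [length_um, 0.0]]),
                          role="hypha")
    medial = PolylineTrace(np.array([[0.0, 0.0], [length_um, 0.0]]),
                           role="medial_path")
    arc = np.arange(0.0, length_um + step / 2, step)
    if width_sigma > 0:
        prof = 1.0 + 3.0 * np.exp(-0.5 * ((arc - peak_arc_um) / width_sigma) ** 2)
    else:
        prof = np.zeros_like(arc)
        prof[int(np.argmin(np.abs(arc - peak_arc_um)))] = 1.0
    cell = CellRecord(cell_id=cell_id, body_axis=body, hyphae=(hypha,),
                      bud_path=None, has_bud=False, stage="hypha_no_bud",
                      medial_path=medial, hypha_start_um=hypha_start_um)
    cell.profile_arc_um = arc
    cell.profiles[channel] = prof
    return cell
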