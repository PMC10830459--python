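"""Process-level allocator tuning.

The daily loop allocates multi-megabyte forcing arrays every simulated
year; with glibc's default mmap threshold each one is returned to the
kernel on free and costs fresh page faults on the next allocation, which
can dominate runtime in containerised environments.  Raising the threshold
keeps those blocks on the heap for reuse.  Set ``INLANDN2O_NO_MALLOC_TUNING``
to disable.
"""

from __future__ import annotations

import ctypes
import os

_M_MMAP_THRESHOLD = -3


def tune_allocator() -> bool:
    if os.environ.get("INLANDN2O_NO_MALLOC_TUNING"):
        return False
    try:
        libc = ctypes.CDLL("libc.so.6")
        return bool(libc.mallopt(_M_MMAP_THRESHOLD, 1 << 30))
    except (OSError, AttributeError):  # non-glibc platform
        return False
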