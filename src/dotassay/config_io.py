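"""Configuration and file-format surface in one namespace.

Convenience re-exports: the implementation lives in :mod:`dotassay.config`
(AssayConfig, load/save) and :mod:`dotassay.io` (video and table I/O).
"""

from .config import (AssayConfig, ConfigError, ValidationError,  # noqa: F401
                     load_config, save_config)
from .io import (FrameStack, InputError, read_events, read_stimulus_log,  # noqa: F401
                 read_tracks, read_video, write_stimulus_log, write_tables)
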