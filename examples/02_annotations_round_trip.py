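"""Write and read LabelImg/Pascal-VOC box annotations.

Internal boxes are 0-based half-open; the XML dialect is 1-based
inclusive.  The conversion is a bijection, so write-then-read returns the
identical list.
"""

import tempfile
from pathlib import Path

from paniclecount import BoundingBox, read_voc_xml, write_voc_xml

boxes = [BoundingBox(0, 0, 10, 10), BoundingBox(120, 40, 133, 72)]
path = Path(tempfile.mkdtemp()) / "frame_0001.xml"
write_voc_xml(boxes, {"height": 256, "width": 256}, path)
print(path.read_text())

recovered = read_voc_xml(path, (256, 256))
print("round-trip identical:", recovered == boxes)
print("first box on disk is (1, 1, 10, 10): 1-based inclusive for the "
      "same 100 pixels the internal (0, 0, 10, 10) covers")
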