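>P02545|PRELAMIN_A_HUMAN synthetic stand-in sequence (664 aa; printed surrogate peptides and processing junctions at published coordinates; filler elsewhere) deletion=607-656
AEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNS
ELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVSELNGRDSQTLAEK
NVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNSELVRAQDSGTLKSVNELAGRTDQS
GVEKLNAGSETRAEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLR
DLQSVAEKGTNSELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVSE
LNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNSELVRAQDSGTLK
SVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDS
QVLKSETNAGLRDLQSVAEKGTNSELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETR
AEGLQDSKTVSELNGRDSQTLAEKNVGSELTRAGDSQVLKSETNAGLRDLQSVAEKGTNS
ELVRAQDSGTLKSVNELAGRTDQSGVEKLNAGSETRAEGLQDSKTVLCGTCGQPADKASA
SGSGAQGATQSLKHSNAGTVSRQKSVGGSGGGSFGDNLVTRSYHELSTASSGNQARSPQN
CSIM
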