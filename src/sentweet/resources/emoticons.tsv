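:)	<smile>
:-)	<smile>
:))	<smile>
:D	<smile>
:-D	<smile>
;)	<smile>
;-)	<smile>
:(	<smile>
:-(	<smile>
:'(	<smile>
:'-(	<smile>
:'')	<smile>
D:	<smile>
:P	<smile>
:-P	<smile>
:p	<smile>
:-p	<smile>
:|	<smile>
:-|	<smile>
:/	<smile>
:-/	<smile>
:\	<smile>
:o	<smile>
:O	<smile>
:-O	<smile>
:*	<smile>
<3	<smile>
</3	<smile>
=)	<smile>
=(	<smile>
=D	<smile>
^_^	<smile>
^-^	<smile>
-_-	<smile>
o_O	<smile>
O_o	<smile>
xD	<smile>
XD	<smile>
:3	<smile>
8)	<smile>
8-)	<smile>
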