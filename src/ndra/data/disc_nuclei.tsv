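symbol	example	description
I	pit	short front vowel
E	pet	short front vowel
{	pat	short front vowel
V	putt	short central vowel
Q	pot	short back vowel
U	put	short back vowel
@	another	schwa
i	bean	long front vowel
#	barn	long back vowel
$	born	long back vowel
u	boon	long back vowel
3	burn	long central vowel
1	bay	diphthong
2	buy	diphthong
4	boy	diphthong
5	no	diphthong
6	brow	diphthong
7	peer	diphthong
8	pear	diphthong
9	poor	diphthong
c	timbre	nasalized vowel
q	detente	nasalized vowel
0	lingerie	nasalized vowel
~	bouillon	nasalized vowel
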