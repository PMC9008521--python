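word	score
laughter	8.50
happiness	8.44
love	8.42
happy	8.30
laughed	8.26
laugh	8.22
laughing	8.20
excellent	8.18
joy	8.16
successful	8.16
win	8.12
rainbow	8.10
smile	8.10
won	8.10
smiles	8.05
paradise	8.02
celebration	8.02
enjoyed	8.00
healthy	8.00
music	8.00
celebrating	7.92
congratulations	7.91
weekend	7.84
amazing	7.83
awesome	7.82
vacation	7.82
angels	7.78
friends	7.76
appreciation	7.75
family	7.74
sunshine	7.72
delicious	7.70
beautiful	7.68
fun	7.66
holidays	7.64
loved	7.62
praise	7.60
loves	7.58
kindness	7.56
kisses	7.54
peace	7.52
brilliant	7.50
donate	7.48
gift	7.46
hug	7.44
butterflies	7.42
best	7.40
birthday	7.38
blessed	7.36
wonderful	7.34
health	7.32
friendship	7.30
sweetheart	7.28
cake	7.26
thanks	7.24
puppy	7.22
donation	7.20
holiday	7.18
generous	7.16
kitten	7.14
comedy	7.12
honour	7.10
care	7.08
relax	7.06
proud	7.04
caring	7.02
sunlight	7.00
winner	6.98
supportive	6.96
friendly	6.94
support	6.92
hope	6.90
warmth	6.88
grateful	6.86
kind	6.84
free	6.82
helping	6.80
inspired	6.78
strong	6.76
courage	6.74
dream	6.72
comfort	6.70
heart	6.68
safe	6.66
important	6.64
together	6.62
community	6.60
learning	6.58
listening	6.56
helpful	6.54
welcome	6.52
honest	6.50
open	6.48
kid	6.44
student	6.42
children	6.40
programs	6.38
growth	6.36
awareness	6.34
mindful	6.32
conversation	6.30
calm	6.28
rest	6.26
forward	6.24
talk	6.22
share	6.20
voice	6.18
morning	6.16
home	6.14
book	6.12
sleep	6.10
coffee	6.08
walk	6.06
today	6.04
people	6.02
time	6.00
day	5.98
story	5.96
world	5.94
water	5.90
city	5.86
road	5.82
week	5.78
house	5.74
work	5.70
words	5.66
news	5.62
office	5.58
phone	5.54
school	5.50
question	5.46
moment	5.42
government	5.38
media	5.34
public	5.30
service	5.26
therapy	5.22
doctor	5.18
therapist	5.14
money	5.10
busy	5.06
silence	5.02
waiting	4.98
slow	4.94
rain	4.90
cold	4.86
heavy	4.82
tired	4.78
serious	4.74
difficult	4.70
mental	4.66
strange	4.62
dark	4.58
doubt	4.54
risk	4.50
pressure	4.46
poor	4.42
broken	4.34
worried	4.26
struggle	4.18
alone	4.10
fear	4.02
stress	3.94
anxious	3.86
silent	3.78
hurt	3.70
gun	3.62
lost	3.54
sad	3.46
guns	3.38
angry	3.30
vulnerable	3.22
cry	3.14
crying	3.06
problem	2.98
shocked	2.90
sick	2.82
failure	2.74
illness	2.66
stigma	2.58
disorder	2.50
crisis	2.42
anxiety	2.34
pain	2.26
shooting	2.18
violence	2.10
grief	2.02
depressed	1.98
suffering	1.94
disease	1.90
depression	1.86
abuse	1.82
trauma	1.78
hopeless	1.74
tragedy	1.70
killing	1.66
dead	1.62
death	1.58
murder	1.54
died	1.50
kill	1.46
killed	1.42
war	1.38
terror	1.34
suicide	1.30
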